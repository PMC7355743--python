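"""File formats, run manifests and the stage orchestrator.

Conventions: TSV is tab-separated UTF-8 with a mandatory header and "NA"
for missing; VCF is the minimal biallelic-SNP subset with a GT-only FORMAT
(REF = other allele, ALT = risk allele, 1-based positions, "./." missing);
weights files are 4+ column TSV (snp_id, risk_allele, other_allele, beta).
Every pipeline run emits a JSON manifest recording the subcommand, config
hash, input digests, seeds, package version and thresholds in force.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    DosageMatrix,
    GenotypeMatrix,
    MISSING_ALLELE,
    PANEL_COLUMNS,
    validate_panel,
)
from .errors import ConfigurationError, DataError

__all__ = [
    "read_weights",
    "write_weights",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "write_dosage_tsv",
    "read_cohort",
    "write_cohort",
    "read_weight_status_table",
    "write_manifest",
    "run_pipeline",
]

_NA = "NA"


# ---------------------------------------------------------------------------
# weights / panel


def read_weights(path) -> pd.DataFrame:
    """Read a variant-weights TSV into a validated panel.

    Requires the header columns snp_id, risk_allele, other_allele, beta
    (extra columns such as chrom/pos/freq are preserved); malformed betas
    and duplicate ids are reported with their line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA],
                        keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing weight-file columns {missing}")
    betas = pd.to_numeric(table["beta"], errors="coerce")
    bad = table.index[betas.isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise DataError(
            f"{path}: malformed beta on line {int(bad[0]) + 2}: "
            f"{table.loc[bad[0], 'beta']!r}"
        )
    table["beta"] = betas
    for col in ("pos", "freq"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    dups = table.loc[table["snp_id"].duplicated(), "snp_id"]
    if len(dups):
        raise DataError(f"{path}: duplicate snp_id {dups.iloc[0]!r}")
    return validate_panel(table)


def write_weights(panel: pd.DataFrame, path) -> None:
    validate_panel(panel)
    panel.to_csv(path, sep="\t", index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_vcf(genotypes: GenotypeMatrix, panel: pd.DataFrame, path) -> None:
    """Write calls as a minimal VCF: GT-only FORMAT, one sample column per
    individual, REF = other allele, ALT = risk allele."""
    validate_panel(panel)
    indexed = panel.set_index("snp_id").loc[genotypes.snps]
    chroms = (indexed["chrom"] if "chrom" in indexed.columns
              else pd.Series(["1"] * len(indexed), index=indexed.index))
    poss = (indexed["pos"] if "pos" in indexed.columns
            else pd.Series(np.arange(1, len(indexed) + 1) * 1000,
                           index=indexed.index))
    lines = ["##fileformat=VCFv4.2"]
    for chrom in pd.unique(chroms.astype(str)):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.individuals)
    )
    for j, snp in enumerate(genotypes.snps):
        ref = indexed.at[snp, "other_allele"]
        alt = indexed.at[snp, "risk_allele"]
        cells = []
        for i in range(genotypes.n_individuals):
            a, b = genotypes.alleles[i, j]
            if a == MISSING_ALLELE or b == MISSING_ALLELE:
                cells.append("./.")
            else:
                codes = sorted(0 if x == ref else 1 for x in (a, b))
                cells.append(f"{codes[0]}/{codes[1]}")
        lines.append(
            f"{chroms.loc[snp]}\t{int(poss.loc[snp])}\t{snp}\t{ref}\t{alt}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    reader = VCF(str(path))
    individuals = list(reader.samples)
    snps, columns = [], []
    for variant in reader:
        if len(variant.ALT) != 1:
            raise DataError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                "is not supported"
            )
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise DataError(
                f"non-SNP record at {variant.CHROM}:{variant.POS} ({ref}>{alt})"
            )
        snps.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        col = np.empty((len(individuals), 2), dtype="<U1")
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col[i] = (MISSING_ALLELE, MISSING_ALLELE)
            else:
                col[i] = (ref if a == 0 else alt, ref if b == 0 else alt)
        columns.append(col)
    alleles = (np.stack(columns, axis=1) if columns
               else np.empty((len(individuals), 0, 2), dtype="<U1"))
    return GenotypeMatrix(individuals=individuals, snps=snps, alleles=alleles)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Wide TSV: one row per individual, one column per SNP, two-letter
    genotype strings (e.g. "AG"), NA for missing."""
    cells = np.char.add(genotypes.alleles[:, :, 0], genotypes.alleles[:, :, 1])
    frame = pd.DataFrame(cells, index=pd.Index(genotypes.individuals,
                                               name="individual"),
                         columns=genotypes.snps)
    frame = frame.replace(MISSING_ALLELE * 2, _NA)
    frame.to_csv(path, sep="\t", na_rep=_NA)


def _read_tsv_genotypes(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        na_values=[_NA], keep_default_na=False)
    individuals = frame.index.astype(str).tolist()
    snps = list(frame.columns)
    alleles = np.full((len(individuals), len(snps), 2), MISSING_ALLELE,
                      dtype="<U1")
    values = frame.to_numpy(dtype=object)
    for i in range(len(individuals)):
        for j in range(len(snps)):
            cell = values[i, j]
            if isinstance(cell, str) and len(cell) == 2:
                alleles[i, j] = (cell[0], cell[1])
            elif cell is not None and not pd.isna(cell):
                raise DataError(
                    f"malformed genotype {cell!r} for {individuals[i]} at "
                    f"{snps[j]}"
                )
    return GenotypeMatrix(individuals=individuals, snps=snps, alleles=alleles)


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read genotype calls from a minimal VCF or a wide TSV table."""
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv_genotypes(path)
    raise DataError(f"unknown genotype format {format!r}")


def write_dosage_tsv(dosage: DosageMatrix, path) -> None:
    frame = dosage.to_frame()
    frame.to_csv(path, sep="\t", na_rep=_NA)


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_weight_status_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    needed = {"sex", "age", "overweight", "obesity"}
    missing = needed - set(table.columns)
    if missing:
        raise DataError(f"weight-status table lacks columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# manifests


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    out_dir,
    subcommand: str,
    config: Optional[dict] = None,
    inputs: Optional[dict] = None,
    seed: Optional[int] = None,
    thresholds: Optional[dict] = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "subcommand": subcommand,
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest()[:16],
        "config": json.loads(config_json),
        "inputs": {
            name: _digest(p) for name, p in (inputs or {}).items()
            if Path(p).exists()
        },
        "thresholds": thresholds or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute simulate -> qc -> score (and optional analyses) per config.

    The config maps stage names to their parameters: a ``simulate`` block
    (SimConfig fields) or ``inputs`` block (weights + genotypes paths) must
    supply the genotype source; ``qc`` may override callrate_min/hwe_alpha;
    ``score`` may set the number of quantile strata.  Outputs and a
    manifest are written under ``out_dir``; the dict returned maps stage
    names to their in-memory results.
    """
    from . import genoqc, score as score_mod, simdata

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        if "seed" not in sim_kwargs:
            raise ConfigurationError(
                "stochastic stage 'simulate' requires an explicit seed"
            )
        sim = simdata.SimConfig(**sim_kwargs)
        panel, _ = simdata.simulate_panel(sim)
        genotypes, truth = simdata.simulate_genotypes(panel, sim)
        write_weights(panel, out_dir / "weights.tsv")
        write_genotypes_vcf(genotypes, panel, out_dir / "genotypes.vcf")
        seed = sim.seed
    elif "inputs" in config:
        inputs = config["inputs"]
        if "weights" not in inputs:
            raise ConfigurationError("pipeline config must name a weights file")
        if "genotypes" not in inputs:
            raise ConfigurationError("pipeline config must name a genotypes file")
        panel = read_weights(inputs["weights"])
        genotypes = read_genotypes(inputs["genotypes"],
                                   inputs.get("format", "auto"))
        seed = config.get("seed")
    else:
        raise ConfigurationError(
            "pipeline config must contain a 'simulate' or 'inputs' block"
        )
    results["panel"] = panel
    results["genotypes"] = genotypes

    qc_cfg = config.get("qc", {})
    callrate_min = float(qc_cfg.get("callrate_min", genoqc.DEFAULT_CALLRATE_MIN))
    hwe_alpha = float(qc_cfg.get("hwe_alpha", genoqc.DEFAULT_HWE_ALPHA))
    retained, report = genoqc.qc_filter(genotypes, panel,
                                        callrate_min=callrate_min,
                                        hwe_alpha=hwe_alpha)
    header = (f"# callrate_min={callrate_min}\thwe_alpha={hwe_alpha}\n")
    with open(out_dir / "qc_report.tsv", "w") as fh:
        fh.write(header)
        report.to_csv(fh, sep="\t", index=False)
    results["qc_panel"], results["qc_report"] = retained, report

    kept = genotypes.subset_snps(retained["snp_id"].tolist())
    dosage = genoqc.impute_missing(genoqc.to_dosage(kept, retained))
    scores = score_mod.compute_pgrs(dosage, retained)
    k = int(config.get("score", {}).get("strata", 4))
    strata = score_mod.quantile_strata(scores, k=k)
    table = pd.DataFrame({"pgrs": scores, "stratum": strata})
    table.to_csv(out_dir / "scores.tsv", sep="\t", na_rep=_NA)
    results["scores"] = table

    write_manifest(
        out_dir,
        subcommand="pipeline",
        config=config,
        seed=seed,
        thresholds={"callrate_min": callrate_min, "hwe_alpha": hwe_alpha},
    )
    return results
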