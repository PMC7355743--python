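"""Variant-level genotyping quality control and dosage conversion.

QC mirrors standard candidate-SNP practice: drop a SNP when its call rate
falls below a threshold (default 95%) or when its genotype counts deviate
from Hardy-Weinberg equilibrium by an exact conditional test.  Retained
genotypes are oriented by the weights panel into a risk-allele dosage
matrix (0/1/2 copies), with frequency-based mean imputation of the few
remaining missing calls before scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import (
    DosageMatrix,
    GenotypeMatrix,
    MISSING_ALLELE,
    validate_panel,
)
from .errors import DataError, SnpMismatchError

__all__ = [
    "call_rate",
    "hwe_exact_test",
    "genotype_counts",
    "qc_filter",
    "to_dosage",
    "impute_missing",
    "DEFAULT_CALLRATE_MIN",
    "DEFAULT_HWE_ALPHA",
]

DEFAULT_CALLRATE_MIN = 0.95
#: the HWE rejection threshold used by QC; exposed because different
#: genotyping platforms use anything from 1e-6 to 0.05
DEFAULT_HWE_ALPHA = 1e-3

#: relative tolerance for the "no more probable than observed" tie rule
_TIE_RTOL = 1e-12


def call_rate(genotypes: GenotypeMatrix) -> pd.Series:
    """Fraction of individuals with a non-missing call, per SNP."""
    if genotypes.n_individuals == 0:
        raise DataError("call rate undefined for zero individuals")
    observed = ~genotypes.missing_mask()
    rates = observed.mean(axis=0)
    return pd.Series(rates, index=genotypes.snps, name="call_rate")


def _log_het_probabilities(n_het_values: np.ndarray, n_r: int, n_o: int) -> np.ndarray:
    """Log P(heterozygote count = h | allele counts) under HWE.

    Conditional on the risk/other allele totals ``n_r``/``n_o`` the
    heterozygote count h fully determines the genotype configuration:
    a = (n_r - h)/2 risk homozygotes and b = (n_o - h)/2 other homozygotes.
    """
    n = (n_r + n_o) // 2
    h = n_het_values
    a = (n_r - h) // 2
    b = (n_o - h) // 2
    return (
        gammaln(n + 1) - gammaln(a + 1) - gammaln(h + 1) - gammaln(b + 1)
        + h * np.log(2.0)
        + gammaln(n_r + 1) + gammaln(n_o + 1) - gammaln(2 * n + 1)
    )


def hwe_exact_test(n_rr: int, n_rh: int, n_hh: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Parameters are counts of risk homozygotes, heterozygotes and other-allele
    homozygotes.  Conditional on the observed allele totals, the probability
    of every attainable heterozygote count is evaluated and the p-value is
    the summed probability of all configurations no more probable than the
    observed one (ties included with a small relative tolerance).

    Returns a p-value in (0, 1]; monomorphic SNPs admit a single
    configuration and return exactly 1.0.
    """
    counts = (n_rr, n_rh, n_hh)
    if any(c < 0 for c in counts):
        raise DataError(f"negative genotype count: {counts}")
    if any(int(c) != c for c in counts):
        raise DataError(f"non-integer genotype count: {counts}")
    n_rr, n_rh, n_hh = (int(c) for c in counts)
    n = n_rr + n_rh + n_hh
    if n == 0:
        raise DataError("all genotype counts are zero")

    n_r = 2 * n_rr + n_rh
    n_o = 2 * n_hh + n_rh
    if n_r == 0 or n_o == 0:
        return 1.0

    h_max = min(n_r, n_o)
    h_min = h_max % 2  # parity of allele totals fixes the parity of h
    h_values = np.arange(h_min, h_max + 1, 2)
    log_probs = _log_het_probabilities(h_values, n_r, n_o)
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()

    observed = probs[np.searchsorted(h_values, n_rh)]
    p = float(probs[probs <= observed * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def genotype_counts(genotypes: GenotypeMatrix, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP counts of (risk hom, het, other hom) observed calls."""
    validate_panel(panel)
    panel = panel.set_index("snp_id").loc[genotypes.snps]
    risk = panel["risk_allele"].to_numpy()[None, :, None]
    n_risk_alleles = (genotypes.alleles == risk).sum(axis=2)
    observed = ~genotypes.missing_mask()
    rows = []
    for j, snp in enumerate(genotypes.snps):
        d = n_risk_alleles[observed[:, j], j]
        rows.append(
            {
                "snp_id": snp,
                "n_rr": int((d == 2).sum()),
                "n_rh": int((d == 1).sum()),
                "n_hh": int((d == 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def qc_filter(
    genotypes: GenotypeMatrix,
    panel: pd.DataFrame,
    callrate_min: float = DEFAULT_CALLRATE_MIN,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNPs failing call-rate or Hardy-Weinberg criteria.

    Returns ``(retained_panel, report)``.  The report has one row per input
    SNP with its call rate, HWE p-value and status (``retained``,
    ``dropped_callrate`` or ``dropped_hwe``); call rate is checked first, so
    a SNP failing both criteria is reported under the call-rate reason.
    """
    validate_panel(panel)
    panel_ids = set(panel["snp_id"])
    geno_ids = set(genotypes.snps)
    if panel_ids != geno_ids:
        only_panel = sorted(panel_ids - geno_ids)
        only_geno = sorted(geno_ids - panel_ids)
        raise SnpMismatchError(
            "panel and genotype SNP sets differ "
            f"(only in panel: {only_panel}; only in genotypes: {only_geno})",
            only_left=only_panel,
            only_right=only_geno,
        )

    rates = call_rate(genotypes)
    counts = genotype_counts(genotypes, panel).set_index("snp_id")

    records = []
    for snp in genotypes.snps:
        rate = float(rates[snp])
        c = counts.loc[snp]
        hwe_p = hwe_exact_test(int(c["n_rr"]), int(c["n_rh"]), int(c["n_hh"]))
        if rate < callrate_min:
            status = "dropped_callrate"
        elif hwe_p < hwe_alpha:
            status = "dropped_hwe"
        else:
            status = "retained"
        records.append(
            {"snp_id": snp, "call_rate": rate, "hwe_p": hwe_p, "status": status}
        )
    report = pd.DataFrame(records)
    retained_ids = report.loc[report["status"] == "retained", "snp_id"]
    retained_panel = (
        panel.set_index("snp_id").loc[retained_ids].reset_index()
    )
    return retained_panel, report


def to_dosage(genotypes: GenotypeMatrix, panel: pd.DataFrame) -> DosageMatrix:
    """Count risk alleles per call, oriented by the panel.

    Missing calls propagate to NaN values with the mask set.  A called
    allele outside the SNP's {risk, other} pair is a hard error naming the
    SNP and individual (no strand flipping is attempted).
    """
    validate_panel(panel)
    indexed = panel.set_index("snp_id")
    missing_panel = [s for s in genotypes.snps if s not in indexed.index]
    if missing_panel:
        raise SnpMismatchError(
            f"genotype SNPs absent from panel: {missing_panel}",
            only_right=missing_panel,
        )
    sub = indexed.loc[genotypes.snps]
    risk = sub["risk_allele"].to_numpy()[None, :, None]
    other = sub["other_allele"].to_numpy()[None, :, None]

    alleles = genotypes.alleles
    is_risk = alleles == risk
    is_other = alleles == other
    is_missing = alleles == MISSING_ALLELE
    bad = ~(is_risk | is_other | is_missing)
    if bad.any():
        i, j, _ = np.argwhere(bad)[0]
        raise DataError(
            f"allele {alleles[i, j].tolist()} at SNP {genotypes.snps[j]} for "
            f"individual {genotypes.individuals[i]} is not in the panel pair "
            f"({sub['risk_allele'].iloc[j]}/{sub['other_allele'].iloc[j]})"
        )

    mask = genotypes.missing_mask()
    values = is_risk.sum(axis=2).astype(float)
    values[mask] = np.nan
    return DosageMatrix(
        individuals=list(genotypes.individuals),
        snps=list(genotypes.snps),
        values=values,
        mask=mask,
    )


def impute_missing(dosage: DosageMatrix) -> DosageMatrix:
    """Replace missing dosages by twice the observed risk-allele frequency.

    The imputed value 2*p is the expected dosage under HWE given the SNP's
    observed allele frequency, and preserves each column mean exactly.
    """
    values = dosage.values.copy()
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        empty = [s for s, k in zip(dosage.snps, n_obs) if k == 0]
        raise DataError(f"no observed calls to impute from for SNPs: {empty}")
    col_means = np.nansum(values, axis=0) / n_obs
    fill = np.broadcast_to(col_means, values.shape)
    values = np.where(observed, values, fill)
    return DosageMatrix(
        individuals=list(dosage.individuals),
        snps=list(dosage.snps),
        values=values,
        mask=dosage.mask.copy(),
    )
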