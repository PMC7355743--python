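"""Synthetic cohort generation with known ground truth.

Every downstream stage of the pipeline (QC, scoring, association,
prediction, interaction scans, trajectory classification, RCT interaction
tests) is exercised on cohorts produced here, because the study designs the
package targets — candidate-SNP panels genotyped in small pediatric cohorts
— rarely deposit individual-level data.

The generator emulates:

* a candidate panel of independent biallelic SNPs with per-allele weights
  on the adult-BMI GWAS scale (default 56 SNPs, of which 8 are engineered
  to fail the 95% call-rate criterion and 4 to fail the Hardy-Weinberg
  exact test, leaving 44 after QC);
* Hardy-Weinberg genotypes at configurable allele frequencies, with the
  HWE failures produced by an inbreeding-coefficient distortion whose
  magnitude is solved from the requested rejection power;
* an additive BMI Z-score phenotype with a tunable fraction of variance
  attributable to the weighted score (default 5%);
* lifestyle/environment factors with known score x factor interaction
  coefficients (default 47 factors, matching a typical questionnaire);
* five pubertal obesity / insulin-resistance trajectory groups observed at
  a prepubertal baseline and a pubertal follow-up;
* a two-arm placebo/metformin weight-loss trial with configurable
  treatment and score x treatment effects (default arms 59/65).

All randomness flows from one master seed; each sub-simulation draws from
its own fixed-offset stream so that, e.g., adding SNPs does not perturb
phenotype noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DosageMatrix, GenotypeMatrix, GroundTruth, MISSING_ALLELE
from .errors import ConfigurationError, DataError
from . import genoqc
from .longi import IR_CUTOFFS_DEFAULT, SCHEME1_GROUPS, classify_ir

__all__ = [
    "SimConfig",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_environment",
    "simulate_longitudinal",
    "simulate_rct",
    "required_n_for_hwe_failures",
]

# fixed sub-stream offsets (one RNG stream per sub-simulation)
_STREAM_PANEL = 1
_STREAM_GENO = 2
_STREAM_PHENO = 3
_STREAM_ENV = 4
_STREAM_LONGI = 5
_STREAM_RCT = 6

_BASES = np.array(list("ACGT"))

#: BMI Z cut-offs mimicking overweight/obesity thresholds on a Z scale
DEFAULT_BMIZ_CUTOFFS = (1.04, 1.64)


@dataclass
class SimConfig:
    """Parameters of a synthetic study; defaults mirror the study design
    the package targets (56-SNP panel, 12 engineered QC failures, ~5%
    score-attributable BMI Z variance, 47 lifestyle factors, 59/65 trial
    arms)."""

    n_snps: int = 56
    maf_range: tuple[float, float] = (0.10, 0.50)
    #: half-normal scale of per-allele effects, BMI Z units per allele
    beta_scale: float = 0.03
    n_individuals: int = 600
    #: background missing-call probability for SNPs passing QC
    missing_rate: float = 0.01
    n_qc_fail_callrate: int = 8
    n_qc_fail_hwe: int = 4
    #: fraction of phenotype variance attributable to the weighted score
    h2_target: float = 0.05
    #: factor name (or 0-based index) -> true score x factor coefficient
    gxe_effects: Mapping = field(default_factory=dict)
    seed: int = 0

    # --- secondary knobs -------------------------------------------------
    #: call-rate threshold the engineered failures must violate
    callrate_min: float = 0.95
    #: HWE alpha the engineered failures must be rejected at
    hwe_alpha: float = genoqc.DEFAULT_HWE_ALPHA
    #: rejection probability required of each engineered HWE failure
    hwe_fail_power: float = 0.99
    #: missingness given to call-rate failures (must exceed 1 - callrate_min)
    fail_missing_rate: float = 0.12
    #: fraction of phenotype variance from sex/Tanner/origin covariates
    covariate_h2: float = 0.10
    bmiz_cutoffs: tuple[float, float] = DEFAULT_BMIZ_CUTOFFS
    n_env_factors: int = 47
    #: 'ordinal' gives small-integer questionnaire codes 0..4,
    #: 'continuous' standard normal factors
    env_kind: str = "ordinal"
    #: sizes of the five obesity/IR trajectory groups at recruitment
    group_sizes: tuple[int, ...] = (20, 20, 20, 20, 16)
    #: trajectory group name -> top-tertile odds multiplier for the score
    trajectory_enrichment: Mapping = field(default_factory=dict)
    rct_arm_sizes: tuple[int, int] = (59, 65)
    #: extra mean BMI Z reduction in the treated arm
    rct_treatment_effect: float = 0.15
    #: true score x treatment coefficient on the BMI Z reduction
    rct_interaction: float = 0.0
    rct_noise_sd: float = 0.30

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must lie within (0, 0.5], got {self.maf_range}"
            )
        if not (0.0 <= self.h2_target < 1.0):
            raise ConfigurationError(
                f"h2_target must be in [0, 1), got {self.h2_target}"
            )
        for name in ("n_snps", "n_individuals", "n_qc_fail_callrate",
                     "n_qc_fail_hwe", "n_env_factors"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_qc_fail_callrate + self.n_qc_fail_hwe > self.n_snps:
            raise ConfigurationError(
                "engineered QC failures exceed the panel size: "
                f"{self.n_qc_fail_callrate} + {self.n_qc_fail_hwe} > {self.n_snps}"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.missing_rate > 1.0 - self.callrate_min:
            raise ConfigurationError(
                "background missing_rate would itself push SNPs below the "
                "call-rate threshold"
            )
        if self.fail_missing_rate <= 1.0 - self.callrate_min:
            raise ConfigurationError(
                "fail_missing_rate must exceed 1 - callrate_min so the "
                "engineered call-rate failures actually fail"
            )
        if self.h2_target + self.covariate_h2 >= 1.0:
            raise ConfigurationError(
                "h2_target + covariate_h2 must leave room for noise (< 1)"
            )
        if self.env_kind not in ("ordinal", "continuous"):
            raise ConfigurationError(
                f"env_kind must be 'ordinal' or 'continuous', got {self.env_kind!r}"
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one sub-simulation."""
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# panel


def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a variant panel: ids, coordinates, allele pair and weight.

    Risk-allele frequencies are uniform on ``maf_range``; per-allele
    weights are half-normal with scale ``beta_scale`` (risk alleles are,
    by construction, the BMI-increasing alleles, so weights are positive
    as in GWAS-derived scoring files).
    """
    rng = config.rng(_STREAM_PANEL)
    m = config.n_snps
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    betas = np.abs(rng.normal(0.0, config.beta_scale, size=m))
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)],
                          dtype=int).reshape(m, 2)
    panel = pd.DataFrame(
        {
            "snp_id": [f"rs{900000 + i}" for i in range(m)],
            "chrom": [str(1 + (i % 22)) for i in range(m)],
            "pos": [10_000 * (i + 1) for i in range(m)],
            "risk_allele": _BASES[allele_idx[:, 0]] if m else np.array([], dtype=str),
            "other_allele": _BASES[allele_idx[:, 1]] if m else np.array([], dtype=str),
            "beta": betas,
            "freq": freqs,
        }
    )
    truth = GroundTruth(allele_freqs=freqs, betas=betas)
    return panel, truth


# ---------------------------------------------------------------------------
# genotypes


def required_inbreeding(n: int, alpha: float, power: float) -> float:
    """Inbreeding coefficient giving the exact HWE test roughly ``power``
    at sample size ``n`` and threshold ``alpha``.

    Uses the classical result that the 1-df HWE chi-square statistic is
    approximately n*F_hat^2 with F_hat ~ N(F, 1/n); a 30% safety margin
    absorbs the exact test's conservatism, and the generator additionally
    verifies each engineered SNP by running the test.
    """
    z_crit = math.sqrt(stats.chi2.ppf(1.0 - alpha, df=1))
    z_pow = stats.norm.ppf(power)
    return 1.3 * (z_crit + z_pow) / math.sqrt(n)


_F_MAX = 0.95


def required_n_for_hwe_failures(alpha: float, power: float) -> int:
    """Smallest sample size at which an engineered HWE failure is feasible."""
    z_crit = math.sqrt(stats.chi2.ppf(1.0 - alpha, df=1))
    z_pow = stats.norm.ppf(power)
    return math.ceil((1.3 * (z_crit + z_pow) / _F_MAX) ** 2)


def _distorted_probs(p: float, f: float) -> np.ndarray:
    """Genotype probabilities (dosage 0, 1, 2) with inbreeding coefficient f."""
    q = 1.0 - p
    probs = np.array([q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q])
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def _passes_hwe(dosages: np.ndarray, alpha: float) -> bool:
    p = genoqc.hwe_exact_test(
        int((dosages == 2).sum()), int((dosages == 1).sum()),
        int((dosages == 0).sum()),
    )
    return p >= alpha


def simulate_genotypes(
    panel: pd.DataFrame, config: SimConfig
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw genotype calls for ``n_individuals`` x panel.

    SNPs are drawn independently from Hardy-Weinberg proportions at the
    panel's simulated allele frequencies.  ``n_qc_fail_hwe`` designated
    SNPs are instead drawn with an inbreeding-coefficient distortion strong
    enough that the exact test rejects at ``hwe_alpha``;
    ``n_qc_fail_callrate`` designated SNPs receive ``fail_missing_rate``
    missingness (all other SNPs receive exactly
    ``floor(missing_rate * n)`` missing calls).  Each SNP's engineered QC
    property is verified by running the exact test and re-drawn when a
    sampling fluke would flip it, so the downstream QC outcome of the
    fixture is deterministic by construction.
    """
    if len(panel) == 0:
        raise DataError("cannot simulate genotypes for an empty panel")
    if len(panel) != config.n_snps:
        raise ConfigurationError(
            f"panel has {len(panel)} SNPs but config.n_snps = {config.n_snps}"
        )
    n = config.n_individuals
    if n <= 0:
        raise ConfigurationError("n_individuals must be positive")

    if config.n_qc_fail_hwe > 0:
        n_min = required_n_for_hwe_failures(config.hwe_alpha, config.hwe_fail_power)
        if n < n_min:
            raise ConfigurationError(
                f"n_individuals={n} is too small to engineer HWE failures "
                f"with power {config.hwe_fail_power} at alpha "
                f"{config.hwe_alpha}; need at least n={n_min}"
            )
        f_fail = min(required_inbreeding(n, config.hwe_alpha,
                                         config.hwe_fail_power), _F_MAX)
    else:
        f_fail = 0.0

    rng = config.rng(_STREAM_GENO)
    m = len(panel)
    if "freq" in panel.columns:
        freqs = panel["freq"].to_numpy(dtype=float)
    else:  # externally supplied panel without frequencies
        freqs = config.rng(_STREAM_PANEL).uniform(
            config.maf_range[0], config.maf_range[1], size=m
        )

    order = rng.permutation(m)
    fail_callrate = set(order[: config.n_qc_fail_callrate].tolist())
    fail_hwe = set(
        order[config.n_qc_fail_callrate:
              config.n_qc_fail_callrate + config.n_qc_fail_hwe].tolist()
    )

    dosages = np.empty((n, m), dtype=np.int8)
    max_redraws = 200
    for j in range(m):
        p = freqs[j]
        if j in fail_hwe:
            probs = _distorted_probs(p, f_fail)
            want_pass = False
        else:
            probs = _distorted_probs(p, 0.0)
            want_pass = True
        for attempt in range(max_redraws):
            d = rng.choice(3, size=n, p=probs)
            if _passes_hwe(d, config.hwe_alpha) == want_pass:
                break
        else:  # pragma: no cover - power/alpha make this astronomically rare
            raise RuntimeError(
                f"could not realise the engineered HWE property of SNP {j} "
                f"after {max_redraws} draws"
            )
        dosages[:, j] = d

    # allele-pair representation oriented risk/other
    risk = panel["risk_allele"].to_numpy()
    other = panel["other_allele"].to_numpy()
    alleles = np.empty((n, m, 2), dtype="<U1")
    alleles[:, :, 0] = np.where(dosages >= 1, risk, other)
    alleles[:, :, 1] = np.where(dosages == 2, risk, other)

    # missingness: exact counts so call rates are deterministic
    n_miss_clean = int(math.floor(config.missing_rate * n))
    n_miss_fail = max(int(math.ceil(config.fail_missing_rate * n)),
                      int(math.floor((1.0 - config.callrate_min) * n)) + 1)
    for j in range(m):
        k = n_miss_fail if j in fail_callrate else n_miss_clean
        if k > 0:
            rows = rng.choice(n, size=k, replace=False)
            alleles[rows, j, :] = MISSING_ALLELE

    genotypes = GenotypeMatrix(
        individuals=[f"ind{i + 1:05d}" for i in range(n)],
        snps=panel["snp_id"].tolist(),
        alleles=alleles,
    )
    snp_ids = panel["snp_id"].to_numpy()
    truth = GroundTruth(
        allele_freqs=freqs,
        betas=panel["beta"].to_numpy(),
        qc_fail_callrate=tuple(sorted(snp_ids[sorted(fail_callrate)])),
        qc_fail_hwe=tuple(sorted(snp_ids[sorted(fail_hwe)])),
        extras={"inbreeding_f": f_fail},
    )
    return genotypes, truth


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    dosage: DosageMatrix, panel: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Build a cross-sectional cohort table on top of a complete dosage matrix.

    BMI Z is the sum of a standardized genetic-score signal scaled so that
    its variance share equals ``h2_target`` in expectation, covariate
    effects (sex, Tanner stage, recruitment origin) carrying
    ``covariate_h2`` of the variance, and Gaussian noise.  Weight status is
    derived from the configurable BMI Z cut-offs (normal weight /
    overweight / obesity).
    """
    if not dosage.complete:
        raise DataError("phenotype simulation needs a complete dosage matrix "
                        "(impute or drop missing calls first)")
    if config.h2_target >= 1.0:
        raise ConfigurationError("h2_target must be < 1")
    panel = panel.set_index("snp_id").loc[dosage.snps]
    betas = panel["beta"].to_numpy(dtype=float)
    n = dosage.n_individuals
    rng = config.rng(_STREAM_PHENO)

    raw_score = dosage.values @ betas
    sd_s = float(raw_score.std(ddof=0))
    h2 = config.h2_target
    if sd_s > 0 and h2 > 0:
        z = (raw_score - raw_score.mean()) / sd_s
        genetic = math.sqrt(h2) * z
        slope = math.sqrt(h2) / sd_s
    else:
        genetic = np.zeros(n)
        slope = 0.0

    sex = rng.choice(["male", "female"], size=n)
    origin = rng.choice(["Zaragoza", "Santiago", "Cordoba"], size=n)
    tanner_num = rng.integers(1, 6, size=n)
    tanner = np.array(["I", "II", "III", "IV", "V"])[tanner_num - 1]
    age = 6.0 + 1.8 * (tanner_num - 1) + rng.uniform(0.0, 2.0, size=n)

    cov_raw = (
        0.4 * (sex == "male").astype(float)
        + 0.25 * (tanner_num - 1)
        + 0.3 * (origin == "Cordoba").astype(float)
    )
    sd_c = cov_raw.std(ddof=0)
    if sd_c > 0 and config.covariate_h2 > 0:
        covariate = math.sqrt(config.covariate_h2) * (cov_raw - cov_raw.mean()) / sd_c
    else:
        covariate = np.zeros(n)

    noise_sd = math.sqrt(max(1.0 - h2 - config.covariate_h2, 0.0))
    noise = rng.normal(0.0, noise_sd, size=n)
    bmi_z = genetic + covariate + noise

    ow_cut, ob_cut = config.bmiz_cutoffs
    weight_status = np.where(bmi_z >= ob_cut, "OB",
                             np.where(bmi_z >= ow_cut, "OW", "NW"))

    cohort = pd.DataFrame(
        {
            "id": dosage.individuals,
            "sex": sex,
            "age": age,
            "tanner": tanner,
            "origin": origin,
            "pgrs": raw_score,
            "bmi_z": bmi_z,
            "weight_status": weight_status,
        }
    )
    var_y = float(bmi_z.var(ddof=0))
    truth = GroundTruth(
        betas=betas,
        h2_target=h2,
        realized_h2=float(genetic.var(ddof=0) / var_y) if var_y > 0 else 0.0,
        bmi_z_per_score=slope,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# environment factors


def _env_names(k: int) -> list[str]:
    return [f"env_{i + 1:02d}" for i in range(k)]


def _resolve_gxe_effects(config: SimConfig) -> dict[str, float]:
    names = _env_names(config.n_env_factors)
    resolved: dict[str, float] = {}
    for key, value in dict(config.gxe_effects).items():
        if isinstance(key, int):
            if not 0 <= key < config.n_env_factors:
                raise ConfigurationError(
                    f"gxe_effects index {key} outside 0..{config.n_env_factors - 1}"
                )
            name = names[key]
        else:
            name = str(key)
            if name not in names:
                raise ConfigurationError(f"unknown environment factor {name!r}")
        resolved[name] = float(value)
    return resolved


def simulate_environment(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Append ``n_env_factors`` questionnaire columns to a cohort.

    Factors named in ``gxe_effects`` modify BMI Z by
    ``coefficient * pgrs * factor`` — exactly the product term the
    interaction scan estimates — while all other factors are pure noise.
    Ordinal factors take small-integer codes 0..4 (questionnaire style);
    continuous factors are standard normal.
    """
    for col in ("bmi_z", "pgrs"):
        if col not in cohort.columns:
            raise DataError(f"cohort lacks required column {col!r}")
    effects = _resolve_gxe_effects(config)
    n_nonzero = sum(1 for v in effects.values() if v != 0.0)
    if config.n_env_factors < n_nonzero:
        raise ConfigurationError(
            f"{n_nonzero} nonzero interaction effects configured but only "
            f"{config.n_env_factors} factors requested"
        )
    rng = config.rng(_STREAM_ENV)
    n = len(cohort)
    out = cohort.copy()
    bmi_z = out["bmi_z"].to_numpy(dtype=float).copy()
    pgrs = out["pgrs"].to_numpy(dtype=float)
    for name in _env_names(config.n_env_factors):
        if config.env_kind == "ordinal":
            factor = rng.integers(0, 5, size=n).astype(float)
        else:
            factor = rng.normal(0.0, 1.0, size=n)
        out[name] = factor
        coef = effects.get(name, 0.0)
        if coef != 0.0:
            bmi_z = bmi_z + coef * pgrs * factor
    out["bmi_z"] = bmi_z
    return out


# ---------------------------------------------------------------------------
# longitudinal trajectories


def _truncnorm_band(rng, lo_q: float, hi_q: float, size: int) -> np.ndarray:
    """Standard-normal draws restricted to the quantile band [lo_q, hi_q)."""
    u = rng.uniform(lo_q, hi_q, size=size)
    return stats.norm.ppf(u)


# per-group (weight at T0, IR at T0, weight at T1, IR at T1); weight is the
# pooled OW/OB class for the four non-reference groups; names and mapping
# are shared with the trajectory classifier
_GROUP_SPECS = {name: key for key, name in SCHEME1_GROUPS.items()}


def _draw_bmi_z(rng, weight_class: str, cutoffs: tuple[float, float],
                size: int) -> np.ndarray:
    ow, ob = cutoffs
    if weight_class == "NW":
        return rng.uniform(-1.5, ow - 0.1, size=size)
    # pooled overweight/obesity: half OW band, half OB band
    half = rng.random(size) < 0.5
    vals = np.where(
        half,
        rng.uniform(ow + 0.05, ob - 0.05, size=size),
        rng.uniform(ob + 0.05, ob + 1.8, size=size),
    )
    return vals


def _draw_homa(rng, ir: bool, cutoff: np.ndarray | float,
               size: int) -> np.ndarray:
    cutoff = np.broadcast_to(np.asarray(cutoff, dtype=float), (size,))
    if ir:
        return cutoff + rng.uniform(0.05, 3.0, size=size)
    return np.maximum(cutoff - rng.uniform(0.1, 2.0, size=size), 0.3)


def simulate_longitudinal(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-timepoint cohort: prepubertal baseline (Tanner I) and pubertal
    follow-up (Tanner II-V) with BMI Z and HOMA-IR on the correct side of
    the insulin-resistance cut-offs for each trajectory group.

    ``trajectory_enrichment`` maps a group name to a top-tertile odds
    multiplier for the genetic score (e.g. ``{"OWOB_persistent_IR": 3.0}``
    makes persistently obese-IR children three times as likely, in odds,
    to carry a top-tertile score).
    """
    sizes = tuple(int(s) for s in config.group_sizes)
    if len(sizes) != len(_GROUP_SPECS):
        raise ConfigurationError(
            f"group_sizes must have {len(_GROUP_SPECS)} entries, got {len(sizes)}"
        )
    if any(s < 0 for s in sizes):
        raise ConfigurationError("group sizes must be non-negative")
    enrichment = dict(config.trajectory_enrichment)
    unknown = set(enrichment) - set(_GROUP_SPECS)
    if unknown:
        raise ConfigurationError(f"unknown trajectory groups: {sorted(unknown)}")

    rng = config.rng(_STREAM_LONGI)
    cutoffs = IR_CUTOFFS_DEFAULT
    score_mu, score_sd = 1.18, 0.13  # realistic weighted-score scale

    rows = []
    truth_labels = {}
    idx = 0
    for (group, spec), size in zip(_GROUP_SPECS.items(), sizes):
        w0, ir0, w1, ir1 = spec
        mult = float(enrichment.get(group, 1.0))
        # odds of a top-tertile score: baseline 1/2 (prob 1/3), scaled by mult
        p_top = mult / (mult + 2.0)
        for _ in range(size):
            idx += 1
            ind = f"L{idx:04d}"
            sex = rng.choice(["male", "female"])
            origin = rng.choice(["Zaragoza", "Santiago", "Cordoba"])
            top = rng.random() < p_top
            band = (2.0 / 3.0, 1.0) if top else (0.0, 2.0 / 3.0)
            score = score_mu + score_sd * float(_truncnorm_band(rng, *band, 1)[0])

            age0 = float(rng.uniform(6.0, 10.0))
            elapsed = float(rng.uniform(2.0, 5.0))
            tanner1 = str(rng.choice(["II", "III", "IV", "V"]))
            cut1 = (cutoffs.pubertal_boys if sex == "male"
                    else cutoffs.pubertal_girls)
            bmi0 = float(_draw_bmi_z(rng, w0, config.bmiz_cutoffs, 1)[0])
            bmi1 = float(_draw_bmi_z(rng, w1, config.bmiz_cutoffs, 1)[0])
            homa0 = float(_draw_homa(rng, ir0, cutoffs.prepubertal, 1)[0])
            homa1 = float(_draw_homa(rng, ir1, cut1, 1)[0])
            common = dict(id=ind, sex=sex, origin=origin, pgrs=score, group=group)
            rows.append(dict(common, timepoint="T0", tanner="I", age=age0,
                             bmi_z=bmi0, homa_ir=homa0))
            rows.append(dict(common, timepoint="T1", tanner=tanner1,
                             age=age0 + elapsed, bmi_z=bmi1, homa_ir=homa1))
            truth_labels[ind] = group

    cohort = pd.DataFrame(rows)
    truth = GroundTruth(
        group_labels=pd.Series(truth_labels, name="group"),
        extras={"score_mu": score_mu, "score_sd": score_sd,
                "enrichment": enrichment},
    )
    # sanity: generated values classify as intended
    if len(cohort):
        t0 = cohort[cohort["timepoint"] == "T0"]
        assert all(
            classify_ir(h, s, "I", cutoffs) == _GROUP_SPECS[g][1]
            for h, s, g in zip(t0["homa_ir"], t0["sex"], t0["group"])
        )
    return cohort, truth


# ---------------------------------------------------------------------------
# RCT


def simulate_rct(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-arm placebo/treatment trial with two timepoints per child.

    The BMI Z reduction (T0 - T1, positive = weight-status improvement)
    is ``intercept + treatment_effect * treated + rct_interaction * pgrs *
    treated + noise``; ground truth records both effects.
    """
    n_placebo, n_treated = (int(a) for a in config.rct_arm_sizes)
    if n_placebo < 0 or n_treated < 0:
        raise ConfigurationError("arm sizes must be non-negative")
    n = n_placebo + n_treated
    rng = config.rng(_STREAM_RCT)

    arm = np.array(["placebo"] * n_placebo + ["treated"] * n_treated)
    sex = rng.choice(["male", "female"], size=n)
    tanner = rng.choice(["I", "II", "III", "IV", "V"], size=n)
    score = rng.normal(1.18, 0.13, size=n)
    bmi_z0 = rng.normal(2.5, 0.6, size=n)  # obesity cohort at baseline
    treated = (arm == "treated").astype(float)

    reduction = (
        0.05
        + config.rct_treatment_effect * treated
        + config.rct_interaction * score * treated
        + rng.normal(0.0, config.rct_noise_sd, size=n)
    )
    bmi_z1 = bmi_z0 - reduction

    ids = [f"R{i + 1:04d}" for i in range(n)]
    base = pd.DataFrame(
        {"id": ids, "arm": arm, "sex": sex, "tanner": tanner, "pgrs": score}
    )
    t0 = base.assign(timepoint="T0", bmi_z=bmi_z0)
    t1 = base.assign(timepoint="T1", bmi_z=bmi_z1)
    cohort = (
        pd.concat([t0, t1], ignore_index=True)
        .sort_values(["id", "timepoint"], kind="stable")
        .reset_index(drop=True)
    )
    truth = GroundTruth(
        treatment_effect=config.rct_treatment_effect,
        interaction_effect=config.rct_interaction,
    )
    return cohort, truth
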