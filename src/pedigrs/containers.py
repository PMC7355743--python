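"""Core in-memory containers shared by all pipeline stages.

The tabular objects are thin conventions over :class:`pandas.DataFrame`
(validated by helper functions) rather than bespoke classes; matrix-shaped
genotype data get small dataclasses because they carry an alignment contract
(individuals x SNPs) that a bare DataFrame does not express well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

#: sentinel used for a missing allele inside a genotype call
MISSING_ALLELE = "."

PANEL_COLUMNS = ("snp_id", "risk_allele", "other_allele", "beta")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a variant panel table and return it unchanged.

    A panel holds one row per SNP: its identifier, the risk allele whose
    count enters the score, the alternative allele, and the per-allele
    weight (beta, in BMI Z units per allele).
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise DataError(f"panel is missing required columns: {missing}")
    if panel["snp_id"].duplicated().any():
        dups = panel.loc[panel["snp_id"].duplicated(), "snp_id"].tolist()
        raise DataError(f"duplicate snp_id in panel: {dups}")
    same = panel["risk_allele"] == panel["other_allele"]
    if same.any():
        raise DataError(
            "risk_allele equals other_allele for "
            f"{panel.loc[same, 'snp_id'].tolist()}"
        )
    if not np.isfinite(panel["beta"].to_numpy(dtype=float)).all():
        raise DataError("non-finite beta in panel")
    return panel


@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotype calls for individuals x SNPs.

    ``alleles`` has shape ``(n_individuals, n_snps, 2)`` holding single-base
    strings; both entries equal :data:`MISSING_ALLELE` for a missing call.
    """

    individuals: list[str]
    snps: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        n, m = len(self.individuals), len(self.snps)
        if self.alleles.shape != (n, m, 2):
            raise DataError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {m} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        """Boolean (individuals x SNPs) array, True where the call is missing."""
        return (self.alleles == MISSING_ALLELE).any(axis=2)

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: j for j, s in enumerate(self.snps)}
        unknown = [s for s in snp_ids if s not in index]
        if unknown:
            raise DataError(f"unknown SNPs requested: {unknown}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snps=list(snp_ids),
            alleles=self.alleles[:, cols, :],
        )


@dataclass
class DosageMatrix:
    """Risk-allele counts for individuals x SNPs.

    ``values`` are in {0, 1, 2} where observed (fractional after mean
    imputation); ``mask`` is True where the original call was missing.
    """

    individuals: list[str]
    snps: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, m = len(self.individuals), len(self.snps)
        if self.values.shape != (n, m) or self.mask.shape != (n, m):
            raise DataError("dosage value/mask shape mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def complete(self) -> bool:
        """True when no cell is flagged missing-and-unimputed."""
        return not np.isnan(self.values).any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.individuals, name="individual"),
            columns=self.snps,
        )

    def copy(self) -> "DosageMatrix":
        return replace(
            self,
            individuals=list(self.individuals),
            snps=list(self.snps),
            values=self.values.copy(),
            mask=self.mask.copy(),
        )


@dataclass
class AssocResult:
    """One fitted model term: estimate, uncertainty and test."""

    term: str
    estimate: float
    se: float
    stat: float
    p: float
    ci_lo: float
    ci_hi: float
    n_used: int
    #: exp(estimate) for logistic terms, None for linear ones
    odds_ratio: Optional[float] = None
    #: exp(0.1 * estimate): odds ratio per 0.1-unit increase of the exposure
    odds_ratio_per_tenth: Optional[float] = None
    #: model-specific extras (e.g. variance components of a mixed model)
    extra: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "term": self.term, "estimate": self.estimate, "se": self.se,
            "stat": self.stat, "p": self.p, "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi, "n_used": self.n_used,
            "odds_ratio": self.odds_ratio,
        }


@dataclass
class VarianceExplained:
    """Share of outcome variability attributable to a model / component.

    ``full_model_r2`` is the (adjusted or plain) R-squared of the full model;
    ``component_r2`` the partial contribution of the exposure (R2_full minus
    R2 without the exposure).  For logistic fits ``d2`` is the deviance-based
    1 - dev_full/dev_null and ``pseudo_r2`` the Nagelkerke statistic; the
    latter is what epidemiological reports often label a SNP-heritability
    style quantity.
    """

    full_model_r2: float
    component_r2: float
    d2: Optional[float] = None
    pseudo_r2: Optional[float] = None


@dataclass
class ScoreSummary:
    """Distributional summary of a score vector."""

    mean: float
    sd: float
    lilliefors_d: float
    lilliefors_p: float
    n: int


@dataclass
class RocResult:
    """AUC with a 95% confidence interval and the sample bookkeeping."""

    auc: float
    ci_lo: float
    ci_hi: float
    n_cases: int
    n_controls: int
    n_train: int = 0
    n_test: int = 0
    predictors: tuple[str, ...] = ()


@dataclass
class InteractionResult:
    """Score x factor product-term inference from one moderated regression."""

    factor: str
    beta3: float
    se: float
    t: float
    p: float
    ci_lo: float
    ci_hi: float
    n_used: int
    fdr: Optional[float] = None
    error: Optional[str] = None


@dataclass
class GroundTruth:
    """Known parameters of a simulation, recorded for downstream checks."""

    allele_freqs: Optional[np.ndarray] = None
    betas: Optional[np.ndarray] = None
    qc_fail_callrate: tuple[str, ...] = ()
    qc_fail_hwe: tuple[str, ...] = ()
    h2_target: Optional[float] = None
    realized_h2: Optional[float] = None
    #: true coefficient of BMI Z on the raw (unstandardised) score
    bmi_z_per_score: Optional[float] = None
    gxe_effects: dict = field(default_factory=dict)
    group_labels: Optional[pd.Series] = None
    treatment_effect: Optional[float] = None
    interaction_effect: Optional[float] = None
    extras: dict = field(default_factory=dict)
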