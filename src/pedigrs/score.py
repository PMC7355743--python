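"""Weighted polygenic risk score computation and stratification.

The score of individual j is the raw weighted sum over the panel's SNPs of
the risk-allele dosage times the per-allele weight,

    score_j = sum_i beta_i * dosage_ji,

with no division by the number of SNPs or the weight total.  Individuals
are optionally partitioned into score tertiles or quartiles for
contrast-style analyses, and the distribution is summarised with a
Lilliefors normality test (Kolmogorov-Smirnov with estimated mean and SD,
Monte-Carlo p-value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DosageMatrix, ScoreSummary, validate_panel
from .errors import DataError, SnpMismatchError

__all__ = [
    "compute_pgrs",
    "quantile_strata",
    "dichotomize_top",
    "score_summary",
]


def compute_pgrs(dosage: DosageMatrix, panel: pd.DataFrame) -> pd.Series:
    """Per-individual weighted risk score from a complete dosage matrix.

    Panel betas are aligned to dosage columns by ``snp_id``; column order
    is irrelevant.  The dosage matrix must be complete (impute first).
    """
    validate_panel(panel)
    if not dosage.complete:
        raise DataError("dosage matrix has missing cells; impute before scoring")
    indexed = panel.set_index("snp_id")
    missing = [s for s in dosage.snps if s not in indexed.index]
    extra = [s for s in indexed.index if s not in set(dosage.snps)]
    if missing or extra:
        raise SnpMismatchError(
            f"snp_id mismatch (missing from panel: {missing}; "
            f"absent from dosage: {extra})",
            only_left=extra,
            only_right=missing,
        )
    betas = indexed.loc[dosage.snps, "beta"].to_numpy(dtype=float)
    scores = dosage.values @ betas
    return pd.Series(scores, index=pd.Index(dosage.individuals, name="individual"),
                     name="pgrs")


def quantile_strata(scores: pd.Series, k: int = 4) -> pd.Series:
    """Assign each individual to one of k equal-probability score strata.

    Cut points are the (1/k, ..., (k-1)/k) sample quantiles with the usual
    linear-interpolation convention; values tied with a cut point go to the
    lower stratum.  Labels are ``Q1`` (lowest) .. ``Qk`` (highest).
    """
    scores = pd.Series(scores).astype(float)
    if k < 2:
        raise DataError("k must be at least 2")
    if scores.nunique() < k:
        raise DataError(
            f"need at least {k} distinct score values, got {scores.nunique()}"
        )
    cuts = scores.quantile([i / k for i in range(1, k)]).to_numpy()
    # side='left': values equal to a cut point stay in the lower stratum
    idx = np.searchsorted(cuts, scores.to_numpy(), side="left")
    labels = pd.Series(
        [f"Q{i + 1}" for i in idx], index=scores.index, name="stratum"
    )
    return labels


def dichotomize_top(strata: pd.Series, k: int = 3) -> pd.Series:
    """Indicator of membership in the top stratum (1) vs all lower strata (0)."""
    strata = pd.Series(strata).astype(str)
    top = f"Q{k}"
    return (strata == top).astype(int).rename("top_stratum")


def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance of standardized data from the standard normal CDF."""
    from scipy import stats

    x = np.sort(x)
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, n + 1) / n
    d_plus = np.max(grid - cdf)
    d_minus = np.max(cdf - (grid - 1.0 / n))
    return float(max(d_plus, d_minus))


def score_summary(
    scores: pd.Series,
    mc_reps: int = 2000,
    seed: int = 0,
) -> ScoreSummary:
    """Mean, SD and Lilliefors normality test of a score vector.

    The Lilliefors statistic is the KS distance after estimating mean and
    SD from the data; its null distribution depends on n, so the p-value is
    obtained by seeded Monte-Carlo simulation (``mc_reps`` standard-normal
    samples of the same size).
    """
    x = pd.Series(scores).astype(float).dropna().to_numpy()
    n = x.size
    if n < 5:
        raise DataError(f"need at least 5 observations, got {n}")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise DataError("score vector is constant; normality test undefined")
    d_obs = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    # chunked so memory stays modest at large n
    chunk = max(1, int(2_000_000 // n))
    done = 0
    while done < mc_reps:
        b = min(chunk, mc_reps - done)
        sims = rng.standard_normal((b, n))
        sims.sort(axis=1)
        means = sims.mean(axis=1, keepdims=True)
        sds = sims.std(axis=1, ddof=1, keepdims=True)
        from scipy import stats as _st

        cdf = _st.norm.cdf((sims - means) / sds)
        grid = np.arange(1, n + 1) / n
        d_plus = (grid - cdf).max(axis=1)
        d_minus = (cdf - (grid - 1.0 / n)).max(axis=1)
        d_sim = np.maximum(d_plus, d_minus)
        exceed += int((d_sim >= d_obs).sum())
        done += b
    p = (exceed + 1) / (mc_reps + 1)
    return ScoreSummary(
        mean=float(x.mean()), sd=sd, lilliefors_d=d_obs, lilliefors_p=float(p),
        n=n,
    )
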