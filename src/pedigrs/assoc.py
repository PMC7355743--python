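"""Association models between the genetic score and outcomes.

Thin, opinionated wrappers around statsmodels OLS/Logit that return tidy
result objects: linear and logistic score-outcome models with covariate
adjustment, quantile-stratum contrasts, per-SNP scans, greedy AIC variable
selection, Benjamini-Hochberg FDR adjustment and variance-explained
decompositions (partial R2 for linear models; deviance D2 and Nagelkerke
pseudo-R2 for logistic ones, the latter being what epidemiological reports
often label an h2-style quantity).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import AssocResult, DosageMatrix, VarianceExplained
from .errors import DataError, SeparationError

__all__ = [
    "fit_linear",
    "fit_logistic",
    "quantile_contrast",
    "per_snp_scan",
    "stepwise_aic",
    "bh_fdr",
    "variance_explained",
]


def _encode_covariates(covariates: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Dummy-encode categorical covariates with a first-level reference."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=None if covariates is None else covariates.index)
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            parts.append(s.astype(float).rename(col))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _assemble(
    outcome: pd.Series,
    exposure: Optional[pd.Series],
    covariates: Optional[pd.DataFrame],
) -> tuple[pd.Series, pd.DataFrame]:
    """Align inputs on their index, drop incomplete rows, add a constant."""
    outcome = pd.Series(outcome).astype(float)
    pieces = {"__outcome__": outcome}
    frame = pd.DataFrame(pieces)
    if exposure is not None:
        frame["__exposure__"] = pd.Series(exposure).astype(float)
    enc = _encode_covariates(covariates)
    for col in enc.columns:
        frame[col] = enc[col]
    frame = frame.dropna()
    y = frame.pop("__outcome__")
    X = frame
    X.insert(0, "const", 1.0)
    if "__exposure__" in X.columns:
        X = X.rename(columns={"__exposure__": "exposure"})
    return y, X


def _check_design(y: pd.Series, X: pd.DataFrame) -> None:
    n, k = X.shape
    if n <= k:
        raise DataError(f"n={n} rows is not more than {k} parameters")
    if "exposure" in X.columns and X["exposure"].nunique() <= 1:
        raise DataError("exposure is constant on the analysed rows")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < k:
        # name the first column whose removal restores full rank
        culprits = []
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                culprits.append(col)
        raise DataError(f"design matrix is rank deficient; collinear columns "
                        f"involve {culprits or list(X.columns)}")


def _term_result(fit, name: str, n: int, logistic: bool = False) -> AssocResult:
    est = float(fit.params[name])
    se = float(fit.bse[name])
    stat = float(fit.tvalues[name])
    p = float(fit.pvalues[name])
    ci = fit.conf_int().loc[name]
    res = AssocResult(
        term=name, estimate=est, se=se, stat=stat, p=max(p, np.nextafter(0, 1)),
        ci_lo=float(ci[0]), ci_hi=float(ci[1]), n_used=n,
    )
    if logistic:
        res.odds_ratio = float(np.exp(est))
        res.odds_ratio_per_tenth = float(np.exp(0.1 * est))
    return res


def fit_linear(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> tuple[AssocResult, VarianceExplained]:
    """Ordinary least squares of ``outcome`` on ``exposure`` + covariates.

    Returns the exposure term (estimate in outcome units per exposure unit,
    t-based 95% CI) together with the model R2 and the exposure's partial
    R2 (R2 of the full model minus R2 of the model without the exposure).
    """
    y, X = _assemble(outcome, exposure, covariates)
    _check_design(y, X)
    fit = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, X.drop(columns=["exposure"])).fit()
    result = _term_result(fit, "exposure", int(fit.nobs))
    ve = VarianceExplained(
        full_model_r2=float(fit.rsquared),
        component_r2=float(fit.rsquared - reduced.rsquared),
    )
    return result, ve


def _logit_fit(y: pd.Series, X: pd.DataFrame, allow_separation: bool = False):
    """MLE logit; raises SeparationError unless the caller only needs the
    fitted scores for ranking (``allow_separation``), where diverging
    coefficients are harmless."""
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            if allow_separation:
                warnings.simplefilter("ignore")
                # bfgs keeps going where Newton's Hessian goes singular
                fit = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs")
            else:
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not allow_separation and (
        not fit.mle_retvals.get("converged", True)
        or np.any(np.abs(fit.params) > 30)
    ):
        raise SeparationError(
            "logistic fit did not converge to finite estimates "
            "(quasi-separation suspected); largest |coef| = "
            f"{float(np.max(np.abs(fit.params))):.2f}"
        )
    return fit


def _nagelkerke(fit) -> float:
    n = fit.nobs
    cox_snell = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
    max_cs = 1.0 - np.exp(2.0 * fit.llnull / n)
    return float(cox_snell / max_cs) if max_cs > 0 else 0.0


def fit_logistic(
    outcome01: pd.Series,
    exposure: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> tuple[AssocResult, VarianceExplained]:
    """Maximum-likelihood logistic regression of a 0/1 outcome.

    The returned term carries the log-odds estimate, the odds ratio per
    exposure unit and per 0.1 unit (``exp(0.1 * beta)``), Wald CI on the
    link scale; variance explained reports deviance D2 and Nagelkerke
    pseudo-R2.
    """
    y, X = _assemble(outcome01, exposure, covariates)
    classes = set(y.unique())
    if not classes <= {0.0, 1.0}:
        raise DataError(f"outcome must be coded 0/1, saw values {sorted(classes)}")
    if len(classes) < 2:
        raise DataError("both outcome classes must be present")
    _check_design(y, X)
    fit = _logit_fit(y, X)
    reduced = _logit_fit(y, X.drop(columns=["exposure"]))
    result = _term_result(fit, "exposure", int(fit.nobs), logistic=True)
    d2 = float(1.0 - fit.llf / fit.llnull) if fit.llnull != 0 else 0.0
    ve = VarianceExplained(
        full_model_r2=_nagelkerke(fit),
        component_r2=_nagelkerke(fit) - _nagelkerke(reduced),
        d2=d2,
        pseudo_r2=_nagelkerke(fit),
    )
    return result, ve


def quantile_contrast(
    outcome01: pd.Series,
    strata: pd.Series,
    reference: str,
    covariates: Optional[pd.DataFrame] = None,
) -> dict[str, AssocResult]:
    """Odds of the outcome in each stratum relative to a reference stratum.

    One logistic model with an indicator per non-reference stratum; returns
    a mapping stratum -> odds-ratio result.
    """
    strata = pd.Series(strata).astype(str)
    levels = sorted(strata.dropna().unique())
    if reference not in levels:
        raise DataError(f"reference stratum {reference!r} not present in {levels}")
    counts = strata.value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        raise DataError(f"empty strata: {empty}")

    indicators = pd.DataFrame(
        {lv: (strata == lv).astype(float) for lv in levels if lv != reference}
    )
    y, X = _assemble(outcome01, None, covariates)
    indicators = indicators.loc[y.index]
    X = pd.concat([X, indicators], axis=1)
    _check_design(y, X)
    fit = _logit_fit(y, X)
    return {
        lv: _term_result(fit, lv, int(fit.nobs), logistic=True)
        for lv in indicators.columns
    }


def per_snp_scan(
    dosage: DosageMatrix,
    outcome: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Univariate linear association of the outcome with each SNP dosage.

    One OLS fit per SNP; per-SNP failures are recorded in the ``error``
    column rather than aborting the scan.  Benjamini-Hochberg adjusted
    p-values are appended across the successfully fitted SNPs.
    """
    frame = dosage.to_frame()
    frame.index = pd.Index(dosage.individuals)
    rows = []
    for snp in dosage.snps:
        try:
            res, ve = fit_linear(outcome, frame[snp], covariates)
            rows.append(
                {
                    "snp_id": snp, "estimate": res.estimate, "se": res.se,
                    "stat": res.stat, "p": res.p, "ci_lo": res.ci_lo,
                    "ci_hi": res.ci_hi, "n_used": res.n_used,
                    "partial_r2": ve.component_r2, "error": None,
                }
            )
        except (DataError, SeparationError) as exc:
            rows.append({"snp_id": snp, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["error"].isna()
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    return table


def stepwise_aic(
    outcome: pd.Series,
    candidate_dosages: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
) -> list[str]:
    """Greedy bidirectional AIC minimisation over candidate SNP columns.

    Covariates are always retained; candidates are added or dropped one at
    a time while any move lowers the AIC, with ties broken by the first
    candidate in input order.  Returns the selected SNP ids in input order.
    """
    if candidate_dosages.shape[1] < 1:
        raise DataError("need at least one candidate column")
    y, base = _assemble(outcome, None, covariates)
    cands = candidate_dosages.loc[y.index].astype(float)

    def aic_of(selected: tuple[str, ...]) -> float:
        X = pd.concat([base, cands[list(selected)]], axis=1)
        return float(sm.OLS(y, X).fit().aic)

    selected: list[str] = []
    current = aic_of(())
    improved = True
    while improved:
        improved = False
        best_move, best_aic = None, current
        for col in cands.columns:
            if col in selected:
                trial = tuple(c for c in selected if c != col)
            else:
                trial = tuple(selected) + (col,)
            a = aic_of(trial)
            if a < best_aic - 1e-10:
                best_move, best_aic = col, a
        if best_move is not None:
            if best_move in selected:
                selected.remove(best_move)
            else:
                selected.append(best_move)
            current = best_aic
            improved = True
    return [c for c in cands.columns if c in selected]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorting the m raw p-values ascending, the adjusted value of the i-th is
    ``min_{j>=i}(p_j * m / j)`` capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("pvalues must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def variance_explained(fit_full, fit_reduced) -> VarianceExplained:
    """Outcome variability attributable to the terms the full model adds.

    Accepts two fitted statsmodels results on identical rows, the reduced
    model nested in the full one.  Linear fits report the R2 difference;
    logistic fits report deviance D2 and the Nagelkerke difference.
    """
    if int(fit_full.nobs) != int(fit_reduced.nobs):
        raise DataError(
            f"models fitted on different n: {int(fit_full.nobs)} vs "
            f"{int(fit_reduced.nobs)}"
        )
    full_cols = set(np.atleast_1d(fit_full.model.exog_names))
    red_cols = set(np.atleast_1d(fit_reduced.model.exog_names))
    if not red_cols <= full_cols:
        raise DataError("reduced model is not nested in the full model")
    if hasattr(fit_full, "rsquared"):
        return VarianceExplained(
            full_model_r2=float(fit_full.rsquared),
            component_r2=float(fit_full.rsquared - fit_reduced.rsquared),
        )
    d2 = float(1.0 - fit_full.llf / fit_full.llnull)
    return VarianceExplained(
        full_model_r2=_nagelkerke(fit_full),
        component_r2=_nagelkerke(fit_full) - _nagelkerke(fit_reduced),
        d2=d2,
        pseudo_r2=_nagelkerke(fit_full),
    )
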