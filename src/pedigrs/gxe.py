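"""Gene x environment interaction scan via moderated regression.

For each lifestyle factor E, the model

    BMI Z = b0 + b1*score + b2*E + b3*(score x E) + b4*Origin + b5*Tanner + e

is fitted by OLS and inference focuses on the product-term coefficient b3
(two-sided marginal t-test, asymptotically equivalent to the 1-df
likelihood-ratio test).  The scan runs one such model per factor with
complete cases per factor, applies Benjamini-Hochberg FDR across the whole
scan, and supports the +/-1 SD score stratification used for interaction
plots.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import InteractionResult
from .errors import DataError
from . import assoc

__all__ = ["interaction_fit", "interaction_scan", "stratify_for_plot"]

DEFAULT_COVARIATES = ("origin", "tanner")


def interaction_fit(
    cohort: pd.DataFrame,
    factor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "bmi_z",
    score_col: str = "pgrs",
    center: bool = False,
) -> InteractionResult:
    """Moderated regression of the outcome on score, factor and their product.

    The factor must be quantitative or ordinal-coded and non-constant on
    the analysed (complete-case) rows.  ``center`` subtracts means from the
    score and factor before forming the product — the product-term estimate
    is unchanged, only main effects re-parameterise — and is available for
    numerically ill-conditioned factors.
    """
    for col in (outcome, score_col, factor, *covariates):
        if col not in cohort.columns:
            raise DataError(f"cohort lacks column {col!r}")
    if not pd.api.types.is_numeric_dtype(cohort[factor]):
        raise DataError(
            f"factor {factor!r} is not numeric; only quantitative or "
            "ordinal-coded factors can enter the product term"
        )
    cols = [outcome, score_col, factor, *covariates]
    data = cohort[cols].dropna()
    if data[factor].nunique() <= 1:
        raise DataError(f"factor {factor!r} is constant on the analysed rows")

    score = data[score_col].astype(float)
    fac = data[factor].astype(float)
    if center:
        score = score - score.mean()
        fac = fac - fac.mean()
    design = pd.DataFrame({"pgrs": score, "factor": fac,
                           "pgrs_x_factor": score * fac})
    enc = assoc._encode_covariates(data[list(covariates)])
    X = pd.concat([design, enc], axis=1)
    X.insert(0, "const", 1.0)
    y = data[outcome].astype(float)
    assoc._check_design(y, X)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["pgrs_x_factor"]
    return InteractionResult(
        factor=factor,
        beta3=float(fit.params["pgrs_x_factor"]),
        se=float(fit.bse["pgrs_x_factor"]),
        t=float(fit.tvalues["pgrs_x_factor"]),
        p=float(fit.pvalues["pgrs_x_factor"]),
        ci_lo=float(ci[0]),
        ci_hi=float(ci[1]),
        n_used=int(fit.nobs),
    )


def interaction_scan(
    cohort: pd.DataFrame,
    factor_list: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "bmi_z",
    score_col: str = "pgrs",
    center: bool = False,
) -> pd.DataFrame:
    """One moderated regression per factor, FDR-adjusted across the scan.

    Per-factor failures (constant or non-numeric factors, collinearity)
    are recorded in the ``error`` column and excluded from the FDR family;
    the output is sorted by p-value.
    """
    if len(factor_list) == 0:
        raise DataError("factor_list is empty")
    rows = []
    for factor in factor_list:
        try:
            res = interaction_fit(cohort, factor, covariates=covariates,
                                  outcome=outcome, score_col=score_col,
                                  center=center)
            rows.append(
                {"factor": factor, "beta3": res.beta3, "se": res.se,
                 "t": res.t, "p": res.p, "ci_lo": res.ci_lo,
                 "ci_hi": res.ci_hi, "n_used": res.n_used, "error": None}
            )
        except DataError as exc:
            rows.append({"factor": factor, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["error"].isna()
    if not ok.any():
        raise DataError("no factor could be fitted; first error: "
                        f"{table['error'].iloc[0]}")
    table["fdr"] = np.nan
    table.loc[ok, "fdr"] = assoc.bh_fdr(table.loc[ok, "p"].to_numpy())
    return table.sort_values("p", na_position="last").reset_index(drop=True)


def stratify_for_plot(
    scores: pd.Series,
    factor: pd.Series,
    outcome: pd.Series,
) -> pd.DataFrame:
    """Outcome-vs-factor slope within three score bands (below mean - SD,
    within one SD, above mean + SD), the stratification interaction plots
    use.  Empty bands are reported with n and no slope."""
    data = pd.DataFrame({
        "score": pd.Series(scores).astype(float),
        "factor": pd.Series(factor).astype(float),
        "outcome": pd.Series(outcome).astype(float),
    }).dropna()
    if data.empty:
        raise DataError("no complete rows to stratify")
    mu = data["score"].mean()
    sd = data["score"].std(ddof=1)
    bands = {
        "low": data["score"] < mu - sd,
        "mid": (data["score"] >= mu - sd) & (data["score"] <= mu + sd),
        "high": data["score"] > mu + sd,
    }
    rows = []
    for name, mask in bands.items():
        sub = data[mask]
        row = {"band": name, "n": int(len(sub)), "slope": np.nan,
               "slope_se": np.nan}
        if len(sub) >= 3 and sub["factor"].nunique() > 1:
            X = sm.add_constant(sub["factor"])
            fit = sm.OLS(sub["outcome"], X).fit()
            row["slope"] = float(fit.params["factor"])
            row["slope_se"] = float(fit.bse["factor"])
        rows.append(row)
    return pd.DataFrame(rows)
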