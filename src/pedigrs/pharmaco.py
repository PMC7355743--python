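"""Score x treatment interaction tests for a two-arm weight-loss trial.

Two parallel parameterisations of the same question — does the genetic
score modify the BMI Z response to treatment?

* a change-score regression: the per-child BMI Z reduction (T0 - T1,
  positive = improvement) regressed on score, arm, their product and
  covariates, reporting the product term;
* a linear mixed-effects model on the long-format data with a random
  intercept per child and fixed effects score, time, arm, all two-way
  products and the three-way score x time x arm term (Wald test).

With balanced, complete two-timepoint data the three-way fixed effect
equals minus the change-score interaction estimate exactly (the delta is
T0 - T1 while the mixed model measures change toward T1); that algebraic
equivalence is the module's central correctness check.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import AssocResult
from .errors import DataError
from . import assoc

__all__ = ["drug_response_interaction", "lme_three_way", "pivot_rct"]

_REQUIRED = ("id", "arm", "timepoint", "bmi_z", "pgrs")


def _validate_rct(rct: pd.DataFrame, need_both_arms: bool = True) -> None:
    missing = [c for c in _REQUIRED if c not in rct.columns]
    if missing:
        raise DataError(f"RCT table lacks columns {missing}")
    arms = set(rct["arm"].astype(str).unique())
    if not arms <= {"placebo", "treated"}:
        raise DataError(f"unexpected arm labels {sorted(arms)}")
    if need_both_arms and arms != {"placebo", "treated"}:
        raise DataError(f"both arms required, got only {sorted(arms)}")
    tps = set(rct["timepoint"].astype(str).unique())
    if not tps <= {"T0", "T1"}:
        raise DataError(f"unexpected timepoints {sorted(tps)}")
    per_id = rct.groupby("id")["arm"].nunique()
    if (per_id > 1).any():
        bad = per_id[per_id > 1].index.tolist()
        raise DataError(f"ids with inconsistent arm labels: {bad}")


def pivot_rct(rct: pd.DataFrame) -> pd.DataFrame:
    """Wide per-child table: baseline/post BMI Z, reduction delta (T0 - T1),
    arm and baseline covariates.  Children missing a timepoint are dropped."""
    _validate_rct(rct, need_both_arms=False)
    wide = rct.pivot_table(index="id", columns="timepoint", values="bmi_z",
                           aggfunc="first")
    if "T0" not in wide.columns or "T1" not in wide.columns:
        raise DataError("RCT table lacks one of the timepoints T0/T1")
    wide = wide.dropna()
    first = rct.drop_duplicates("id").set_index("id")
    out = pd.DataFrame(
        {
            "bmi_z_t0": wide["T0"],
            "bmi_z_t1": wide["T1"],
            "delta": wide["T0"] - wide["T1"],
            "arm": first.loc[wide.index, "arm"],
            "pgrs": first.loc[wide.index, "pgrs"],
        }
    )
    for col in ("sex", "tanner", "origin"):
        if col in first.columns:
            out[col] = first.loc[wide.index, col]
    return out


def drug_response_interaction(
    rct: pd.DataFrame,
    covariates: Sequence[str] = (),
) -> AssocResult:
    """Change-score test of the score x treatment product.

    OLS of the BMI Z reduction (T0 - T1) on score, arm, score x arm and
    any requested baseline covariates; returns the product term (positive
    estimate = larger treated-arm reduction for higher scores).
    """
    _validate_rct(rct)
    wide = pivot_rct(rct)
    if wide["arm"].nunique() < 2:
        raise DataError("both arms must survive the two-timepoint requirement")
    treated = (wide["arm"] == "treated").astype(float)
    design = pd.DataFrame(
        {
            "pgrs": wide["pgrs"].astype(float),
            "treated": treated,
            "pgrs_x_treated": wide["pgrs"].astype(float) * treated,
        },
        index=wide.index,
    )
    missing = [c for c in covariates if c not in wide.columns]
    if missing:
        raise DataError(f"covariates absent from RCT table: {missing}")
    enc = assoc._encode_covariates(wide[list(covariates)]) if covariates else None
    X = design if enc is None else pd.concat([design, enc], axis=1)
    X = X.dropna()
    y = wide.loc[X.index, "delta"].astype(float)
    X.insert(0, "const", 1.0)
    assoc._check_design(y, X)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["pgrs_x_treated"]
    return AssocResult(
        term="pgrs_x_treated",
        estimate=float(fit.params["pgrs_x_treated"]),
        se=float(fit.bse["pgrs_x_treated"]),
        stat=float(fit.tvalues["pgrs_x_treated"]),
        p=float(fit.pvalues["pgrs_x_treated"]),
        ci_lo=float(ci[0]),
        ci_hi=float(ci[1]),
        n_used=int(fit.nobs),
    )


def lme_three_way(
    rct: pd.DataFrame,
    covariates: Sequence[str] = ("tanner",),
) -> AssocResult:
    """Random-intercept mixed model with the score x time x arm fixed effect.

    Fixed effects: score, time (0 at baseline, 1 post), arm, all two-way
    products, the three-way product and the requested covariates; one
    random intercept per child, REML fit, Wald z-test on the three-way
    term.  Data with no repeated measures cannot identify the model.
    """
    _validate_rct(rct)
    data = rct.copy()
    repeats = data.groupby("id")["timepoint"].nunique()
    if (repeats >= 2).mean() <= 0.5:
        raise DataError(
            "a majority of children need both timepoints for the mixed "
            "model; use drug_response_interaction on the deltas instead"
        )
    data["time"] = (data["timepoint"] == "T1").astype(float)
    data["treated"] = (data["arm"] == "treated").astype(float)
    data["pgrs"] = data["pgrs"].astype(float)
    design = pd.DataFrame(
        {
            "pgrs": data["pgrs"],
            "time": data["time"],
            "treated": data["treated"],
            "pgrs_x_time": data["pgrs"] * data["time"],
            "pgrs_x_treated": data["pgrs"] * data["treated"],
            "time_x_treated": data["time"] * data["treated"],
            "pgrs_x_time_x_treated": data["pgrs"] * data["time"] * data["treated"],
        },
        index=data.index,
    )
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise DataError(f"covariates absent from RCT table: {missing}")
    if covariates:
        enc = assoc._encode_covariates(data[list(covariates)])
        design = pd.concat([design, enc], axis=1)
    keep = design.notna().all(axis=1) & data["bmi_z"].notna()
    design = design[keep]
    y = data.loc[keep, "bmi_z"].astype(float)
    groups = data.loc[keep, "id"]
    X = sm.add_constant(design)
    model = sm.MixedLM(y, X, groups=groups)
    fit = model.fit(reml=True)
    term = "pgrs_x_time_x_treated"
    est = float(fit.params[term])
    se = float(fit.bse[term])
    z = est / se
    from scipy.stats import norm

    p = float(2.0 * norm.sf(abs(z)))
    half = norm.ppf(0.975) * se
    return AssocResult(
        term=term, estimate=est, se=se, stat=z, p=p,
        ci_lo=est - half, ci_hi=est + half, n_used=int(fit.nobs),
        extra={
            "random_intercept_var": float(np.asarray(fit.cov_re)[0, 0]),
            "residual_var": float(fit.scale),
        },
    )
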