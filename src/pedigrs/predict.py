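"""Predictive-ability evaluation: split-sample ROC/AUC modelling.

The case/control framing is normal weight vs obesity; cohorts containing
the intermediate overweight class are refused so the exclusion happens
explicitly upstream.  Each candidate predictor set gets a logistic model
fitted on a stratified 75/25 train/test split and an AUC (Mann-Whitney
rank formulation, DeLong 95% CI) measured on the held-out quarter; models
reaching a threshold AUC are merged into one combined model on the
complete-case intersection of their predictors.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import train_test_split as _sk_split

from .containers import RocResult
from .errors import DataError, SeparationError

__all__ = [
    "train_test_split",
    "roc_auc",
    "evaluate_predictors",
    "combine_models",
]

_OUTCOME_COL = "weight_status"


def _binary_outcome(cohort: pd.DataFrame) -> pd.Series:
    if _OUTCOME_COL not in cohort.columns:
        raise DataError(f"cohort lacks the {_OUTCOME_COL!r} column")
    status = cohort[_OUTCOME_COL].astype(str)
    present = set(status.unique())
    if "OW" in present:
        raise DataError(
            "cohort contains the overweight class; exclude it upstream so the "
            "case/control framing is normal weight vs obesity"
        )
    if not present <= {"NW", "OB"}:
        raise DataError(f"unexpected weight statuses {sorted(present - {'NW', 'OB'})}")
    return (status == "OB").astype(int)


def train_test_split(
    cohort: pd.DataFrame, train_frac: float = 0.75, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, outcome-stratified split of a two-class cohort."""
    if not 0.0 < train_frac < 1.0:
        raise DataError(f"train_frac must be in (0, 1), got {train_frac}")
    y = _binary_outcome(cohort)
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise DataError(
            f"each outcome class needs at least 2 members, got {counts.to_dict()}"
        )
    train, test = _sk_split(
        cohort, train_size=train_frac, stratify=y, random_state=int(seed)
    )
    return train, test


def roc_auc(risk_scores: Sequence[float], labels01: Sequence[int]) -> RocResult:
    """AUC by the rank (Mann-Whitney) formulation with DeLong 95% CI.

    Ties between a case and a control count one half.  The DeLong variance
    is computed from placement values; a perfectly separating score has
    zero estimated variance and a degenerate CI at the point estimate.
    """
    x = np.asarray(risk_scores, dtype=float)
    y = np.asarray(labels01, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("risk_scores and labels must be 1-d and equal length")
    if np.isnan(x).any():
        raise DataError("risk scores contain NaN")
    cases = x[y == 1]
    controls = x[y == 0]
    m, n = cases.size, controls.size
    if m == 0 or n == 0:
        raise DataError(f"need both classes, got {m} cases and {n} controls")

    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    # placement values: fraction of the other class each observation beats
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    auc = float(v10.mean())

    if m > 1 and n > 1:
        var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    else:
        var = 0.0
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=auc,
        ci_lo=float(max(0.0, auc - half)),
        ci_hi=float(min(1.0, auc + half)),
        n_cases=m,
        n_controls=n,
    )


def _fit_and_score(
    cohort: pd.DataFrame,
    factors: Sequence[str],
    train_frac: float,
    seed: int,
) -> RocResult:
    from . import assoc

    missing = [f for f in factors if f not in cohort.columns]
    if missing:
        raise DataError(f"predictor columns absent from cohort: {missing}")
    subset = cohort.dropna(subset=list(factors))
    if subset.empty:
        raise DataError(f"no complete cases for predictors {list(factors)}")
    train, test = train_test_split(subset, train_frac=train_frac, seed=seed)

    y_train = _binary_outcome(train)
    y_test = _binary_outcome(test)
    X_train = assoc._encode_covariates(train[list(factors)])
    X_test = assoc._encode_covariates(test[list(factors)])
    X_test = X_test.reindex(columns=X_train.columns, fill_value=0.0)
    X_train.insert(0, "const", 1.0)
    X_test.insert(0, "const", 1.0)
    assoc._check_design(y_train.astype(float), X_train)
    # ranking is all that matters for the AUC, so a separated training fit
    # (e.g. a factor nearly identical to the outcome) is acceptable here
    fit = assoc._logit_fit(y_train.astype(float), X_train,
                           allow_separation=True)
    pred = np.asarray(fit.predict(X_test), dtype=float)

    roc = roc_auc(pred, y_test.to_numpy())
    roc.n_train = len(train)
    roc.n_test = len(test)
    roc.predictors = tuple(factors)
    return roc


def evaluate_predictors(
    cohort: pd.DataFrame,
    factor_sets: Sequence[Sequence[str]],
    train_frac: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Split-sample AUC for each predictor set, complete cases per set.

    Returns one row per factor set with the test AUC, its DeLong CI and the
    per-subset sample bookkeeping; a set whose subset is empty or whose fit
    separates is flagged in ``error`` rather than aborting the table.
    """
    rows = []
    for factors in factor_sets:
        factors = list(factors)
        try:
            roc = _fit_and_score(cohort, factors, train_frac, seed)
            rows.append(
                {
                    "predictors": ",".join(factors), "auc": roc.auc,
                    "ci_lo": roc.ci_lo, "ci_hi": roc.ci_hi,
                    "n": roc.n_train + roc.n_test, "n_cases": roc.n_cases,
                    "n_controls": roc.n_controls, "n_train": roc.n_train,
                    "n_test": roc.n_test, "error": None,
                }
            )
        except (DataError, SeparationError) as exc:
            rows.append({"predictors": ",".join(factors), "error": str(exc)})
    return pd.DataFrame(rows)


def combine_models(
    cohort: pd.DataFrame,
    predictor_table: pd.DataFrame,
    auc_min: float = 0.60,
    train_frac: float = 0.75,
    seed: int = 0,
) -> tuple[RocResult, list[str]]:
    """Merge all predictor sets reaching ``auc_min`` into one model.

    The union of their covariates is fitted on the complete-case
    intersection with a fresh seeded split; returns the combined ROC result
    and the list of qualifying predictor-set strings.
    """
    ok = predictor_table[predictor_table["error"].isna()] \
        if "error" in predictor_table.columns else predictor_table
    qualifying = ok[ok["auc"] >= auc_min]
    if qualifying.empty:
        raise DataError(
            f"no individual model reached the combination threshold "
            f"AUC >= {auc_min}"
        )
    union: list[str] = []
    for preds in qualifying["predictors"]:
        for f in str(preds).split(","):
            if f and f not in union:
                union.append(f)
    roc = _fit_and_score(cohort, union, train_frac, seed)
    return roc, qualifying["predictors"].tolist()
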