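"""Longitudinal obesity / insulin-resistance machinery.

Children observed at a prepubertal baseline (Tanner I) and a pubertal
follow-up (Tanner II-V) are classified at each timepoint by weight status
(normal weight / overweight / obesity, from age- and sex-specific BMI
cut-offs) and insulin-resistance status (HOMA-IR against stage- and
sex-specific cut-offs: >= 2.5 prepubertal, >= 3.38 pubertal boys,
>= 3.90 pubertal girls, all inclusive).  The two-timepoint status pair maps
onto trajectory groups; a dichotomized genetic score (top tertile vs the
rest) is then tested for association with each trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import AssocResult
from .errors import DataError, SeparationError, UnclassifiableTrajectoryError

__all__ = [
    "IrCutoffs",
    "IR_CUTOFFS_DEFAULT",
    "SCHEME1_GROUPS",
    "SCHEME2_GROUPS",
    "classify_ir",
    "classify_weight",
    "make_weight_status_table",
    "trajectory_groups",
    "trajectory_labels",
    "compute_deltas",
    "tertile_trajectory_or",
    "delta_association",
]

TANNER_STAGES = ("I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class IrCutoffs:
    """Inclusive HOMA-IR thresholds for insulin resistance.

    A single prepubertal threshold; pubertal thresholds are sex-specific
    95th-percentile values from a Spanish pediatric reference.
    """

    prepubertal: float = 2.5
    pubertal_boys: float = 3.38
    pubertal_girls: float = 3.90

    def __post_init__(self) -> None:
        if min(self.prepubertal, self.pubertal_boys, self.pubertal_girls) <= 0:
            raise DataError("HOMA-IR cutoffs must be positive")


IR_CUTOFFS_DEFAULT = IrCutoffs()

#: scheme-1 trajectory groups keyed by
#: (weight at T0, IR at T0, weight at T1, IR at T1) with overweight and
#: obesity pooled ("OWOB"); any other combination is unclassifiable
SCHEME1_GROUPS: dict[tuple[str, bool, str, bool], str] = {
    ("NW", False, "NW", False): "NW_nonIR_stable",
    ("OWOB", False, "OWOB", False): "OWOB_nonIR_stable",
    ("OWOB", True, "OWOB", False): "OWOB_IR_resolved",
    ("OWOB", False, "OWOB", True): "OWOB_incident_IR",
    ("OWOB", True, "OWOB", True): "OWOB_persistent_IR",
}

#: scheme-2 groups: weight-only transitions, overweight kept distinct
SCHEME2_GROUPS: dict[tuple[str, str], str] = {
    (w0, w1): f"{w0}->{w1}"
    for w0 in ("NW", "OW", "OB")
    for w1 in ("NW", "OW", "OB")
}


def classify_ir(
    homa: float, sex: str, tanner: str, cutoffs: IrCutoffs = IR_CUTOFFS_DEFAULT
) -> bool:
    """Insulin-resistance status from HOMA-IR, inclusive at the cutoff."""
    if homa is None or not np.isfinite(homa) or homa < 0:
        raise DataError(f"invalid HOMA-IR value {homa!r}")
    if tanner not in TANNER_STAGES:
        raise DataError(f"tanner stage must be one of {TANNER_STAGES}, got {tanner!r}")
    if tanner == "I":
        return homa >= cutoffs.prepubertal
    sex_norm = str(sex).strip().lower() if sex is not None else ""
    if sex_norm in ("male", "m", "boy"):
        return homa >= cutoffs.pubertal_boys
    if sex_norm in ("female", "f", "girl"):
        return homa >= cutoffs.pubertal_girls
    raise DataError(
        f"sex is required at pubertal stages to pick the cutoff, got {sex!r}"
    )


def make_weight_status_table(
    ages: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Synthetic age/sex-specific BMI cut-off table (overweight, obesity).

    A smooth stand-in shaped like published pediatric BMI references: the
    overweight and obesity cut-offs rise with age toward the adult 25 and
    30 kg/m2 values, girls slightly above boys in mid-childhood.  Real
    analyses should load the applicable national reference with
    :func:`pedigrs.io.read_weight_status_table`; this table exists so the
    classifier can be exercised end-to-end on simulated cohorts.
    """
    if ages is None:
        ages = np.arange(2.0, 18.5, 0.5)
    rows = []
    for sex in ("male", "female"):
        bump = 0.3 if sex == "female" else 0.0
        for age in ages:
            t = (age - 2.0) / 16.0
            ow = 17.0 + 8.0 * t**1.3 + bump * np.sin(np.pi * t)
            ob = ow + 2.5 + 2.5 * t
            rows.append(
                {"sex": sex, "age": round(float(age), 2),
                 "overweight": round(float(ow), 3), "obesity": round(float(ob), 3)}
            )
    return pd.DataFrame(rows)


def classify_weight(
    bmi: float, age: float, sex: str, table: pd.DataFrame
) -> str:
    """Weight status NW / OW / OB from BMI against an age-sex cut-off table.

    The nearest half-year row is used; BMI below the overweight cut-off is
    NW, in [overweight, obesity) OW, and at or above the obesity cut-off OB
    (upper class inclusive).
    """
    for col in ("sex", "age", "overweight", "obesity"):
        if col not in table.columns:
            raise DataError(f"weight-status table lacks column {col!r}")
    sex_rows = table[table["sex"] == sex]
    if sex_rows.empty:
        raise DataError(f"no cut-off rows for sex {sex!r}")
    gaps = (sex_rows["age"] - age).abs()
    nearest = gaps.idxmin()
    if gaps[nearest] > 0.5:
        raise DataError(
            f"age {age} outside the cut-off table coverage "
            f"[{sex_rows['age'].min()}, {sex_rows['age'].max()}]"
        )
    row = sex_rows.loc[nearest]
    if row["obesity"] <= row["overweight"]:
        raise DataError("obesity cut-off must exceed the overweight cut-off")
    if bmi >= row["obesity"]:
        return "OB"
    if bmi >= row["overweight"]:
        return "OW"
    return "NW"


def _pool(weight: str) -> str:
    if weight == "NW":
        return "NW"
    if weight in ("OW", "OB"):
        return "OWOB"
    raise DataError(f"unknown weight status {weight!r}")


def trajectory_groups(t0_status, t1_status, scheme: int = 1) -> str:
    """Map a (baseline, follow-up) status pair onto a trajectory group.

    Scheme 1 takes ``(weight, ir)`` tuples at both timepoints and maps
    them onto the five obesity x insulin-resistance groups (overweight and
    obesity pooled); combinations outside the declared mapping — e.g. a
    normal-weight child presenting IR — raise
    :class:`UnclassifiableTrajectoryError` rather than being silently
    binned.  Scheme 2 takes weight-only statuses and labels the transition
    (all nine transitions are defined).
    """
    if scheme == 1:
        (w0, ir0), (w1, ir1) = t0_status, t1_status
        key = (_pool(w0), bool(ir0), _pool(w1), bool(ir1))
        if key not in SCHEME1_GROUPS:
            raise UnclassifiableTrajectoryError(key)
        return SCHEME1_GROUPS[key]
    if scheme == 2:
        key = (str(t0_status), str(t1_status))
        if key not in SCHEME2_GROUPS:
            raise UnclassifiableTrajectoryError(key)
        return SCHEME2_GROUPS[key]
    raise DataError(f"scheme must be 1 or 2, got {scheme!r}")


def trajectory_labels(
    cohort: pd.DataFrame,
    scheme: int = 1,
    cutoffs: IrCutoffs = IR_CUTOFFS_DEFAULT,
    bmiz_cutoffs: tuple[float, float] = (1.04, 1.64),
) -> pd.Series:
    """Label every individual of a two-timepoint long-format cohort.

    Expects columns ``id, timepoint (T0/T1), sex, tanner, bmi_z`` and — for
    scheme 1 — ``homa_ir``.  Weight status is taken from a
    ``weight_status`` column when present, otherwise derived from BMI Z
    against ``bmiz_cutoffs``.  Individuals lacking either timepoint are
    skipped; unclassifiable combinations raise.
    """
    needed = {"id", "timepoint", "bmi_z"}
    if scheme == 1:
        needed |= {"homa_ir", "sex", "tanner"}
    missing = needed - set(cohort.columns)
    if missing:
        raise DataError(f"cohort lacks columns {sorted(missing)}")

    def weight_of(row) -> str:
        if "weight_status" in cohort.columns and pd.notna(row.get("weight_status")):
            return str(row["weight_status"])
        ow, ob = bmiz_cutoffs
        z = row["bmi_z"]
        return "OB" if z >= ob else ("OW" if z >= ow else "NW")

    labels = {}
    for ind, sub in cohort.groupby("id", sort=False):
        by_tp = {tp: rows.iloc[0] for tp, rows in sub.groupby("timepoint")}
        if "T0" not in by_tp or "T1" not in by_tp:
            continue
        r0, r1 = by_tp["T0"], by_tp["T1"]
        if scheme == 1:
            s0 = (weight_of(r0), classify_ir(r0["homa_ir"], r0["sex"],
                                             r0["tanner"], cutoffs))
            s1 = (weight_of(r1), classify_ir(r1["homa_ir"], r1["sex"],
                                             r1["tanner"], cutoffs))
        else:
            s0, s1 = weight_of(r0), weight_of(r1)
        labels[ind] = trajectory_groups(s0, s1, scheme)
    return pd.Series(labels, name="trajectory_group")


def compute_deltas(
    t0_table: pd.DataFrame,
    t1_table: pd.DataFrame,
    direction: str = "T1_minus_T0",
) -> pd.DataFrame:
    """Per-individual change in every shared numeric measurement.

    Tables must be indexed by (or contain) matching ``id`` values; the
    direction is recorded in ``result.attrs['direction']`` so downstream
    reports never carry a silent sign ambiguity.
    """
    if direction not in ("T1_minus_T0", "T0_minus_T1"):
        raise DataError(f"unknown direction {direction!r}")

    def prep(tbl: pd.DataFrame) -> pd.DataFrame:
        if "id" in tbl.columns:
            tbl = tbl.set_index("id")
        return tbl.select_dtypes(include=[np.number])

    a, b = prep(t0_table), prep(t1_table)
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise DataError(f"unmatched individual ids between timepoints: {diff}")
    cols = [c for c in a.columns if c in b.columns]
    b = b.loc[a.index, cols]
    a = a[cols]
    deltas = (b - a) if direction == "T1_minus_T0" else (a - b)
    deltas.attrs["direction"] = direction
    return deltas


def tertile_trajectory_or(
    scores: pd.Series,
    labels: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    reference: str = "NW_nonIR_stable",
    k: int = 3,
) -> pd.DataFrame:
    """Odds of each trajectory group (vs the reference group) for children
    in the top score tertile relative to the lower two tertiles.

    One logistic fit per comparison group, Benjamini-Hochberg adjusted
    across the groups tested.  Groups whose fit separates (e.g. a tertile
    with zero members in the group) are flagged in the ``error`` column.
    """
    from . import assoc, score as score_mod

    scores = pd.Series(scores).astype(float)
    labels = pd.Series(labels).astype(str)
    common = scores.index.intersection(labels.index)
    if reference not in set(labels.loc[common]):
        raise DataError(f"reference group {reference!r} has no members")
    strata = score_mod.quantile_strata(scores.loc[common], k=k)
    top = score_mod.dichotomize_top(strata, k=k)

    groups = [g for g in labels.loc[common].unique() if g != reference]
    if not groups:
        raise DataError("no comparison groups besides the reference")
    rows = []
    for group in sorted(groups):
        mask = labels.loc[common].isin([group, reference])
        idx = common[mask]
        y = (labels.loc[idx] == group).astype(float)
        cov = covariates.loc[idx] if covariates is not None else None
        try:
            res, _ = assoc.fit_logistic(y, top.loc[idx], cov)
            rows.append(
                {"group": group, "estimate": res.estimate, "se": res.se,
                 "stat": res.stat, "p": res.p, "ci_lo": res.ci_lo,
                 "ci_hi": res.ci_hi, "odds_ratio": res.odds_ratio,
                 "n_used": res.n_used, "error": None}
            )
        except (DataError, SeparationError) as exc:
            rows.append({"group": group, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["error"].isna()
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = assoc.bh_fdr(table.loc[ok, "p"].to_numpy())
    return table


def delta_association(
    deltas: pd.DataFrame,
    scores: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Linear association of the score with each longitudinal change.

    One OLS per delta column (complete cases per measurement), tidy output
    sorted by p with a Benjamini-Hochberg column across measurements.
    """
    from . import assoc

    rows = []
    for col in deltas.columns:
        try:
            res, _ = assoc.fit_linear(deltas[col], scores, covariates)
            rows.append(
                {"measurement": col, "estimate": res.estimate, "se": res.se,
                 "stat": res.stat, "p": res.p, "ci_lo": res.ci_lo,
                 "ci_hi": res.ci_hi, "n_used": res.n_used, "error": None}
            )
        except DataError as exc:
            rows.append({"measurement": col, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["error"].isna()
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = assoc.bh_fdr(table.loc[ok, "p"].to_numpy())
    return table.sort_values("p", na_position="last").reset_index(drop=True)
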