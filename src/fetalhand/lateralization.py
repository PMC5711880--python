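"""Frequency-of-use and distribution analyses.

Right-hand-use proportions with binomial tests, total-movement comparison
between handedness groups, the 18 per-condition group comparisons
(Hodges-Lehmann + Welch U, FDR-controlled), and within-subject RH/LH
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fetalhand.data_model import (
    Cohort,
    CountsTable,
    iter_conditions,
)
from fetalhand.errors import DegenerateDataError, ValidationError
from fetalhand.robust_stats import (
    TestResult,
    benjamini_hochberg,
    binomial_test,
    pearson,
    welch_u_test,
    wilcoxon_rank_sum,
)

MIN_GROUP_N = 2  # per-condition minimum sample size for a two-sample test


@dataclass(frozen=True)
class ConditionComparison:
    """One group comparison (right- vs left-handed fetuses) in one condition.

    The estimate orientation is right-handed group minus left-handed group,
    in the metric's units.
    """

    gw: int
    target: str
    hand: str
    metric: str
    n_right_group: int
    n_left_group: int
    result: TestResult | None
    significant: bool = False
    skipped: bool = False
    reason: str = ""


@dataclass(frozen=True)
class TotalsComparison:
    totals: dict[str, int]  # per-fetus movement totals (roster fetuses, zeros kept)
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    result: TestResult


@dataclass(frozen=True)
class WithinSubjectCorrelation:
    """Per-(target x week) Pearson r between per-fetus RH and LH means."""

    metric: str
    coefficients: dict[tuple[str, int], float]  # (target, gw) -> r
    n_fetuses: dict[tuple[str, int], int]
    skipped: dict[tuple[str, int], str]
    median: float
    range: tuple[float, float]


def rh_use_proportion(cohort: Cohort, group: str, gw: int, unit: str = "movements"):
    """Proportion of right-hand use for one handedness group at one week.

    With ``unit='movements'`` (default) the binomial test vs chance 0.5 is
    over movements; with ``unit='fetuses'`` it is over fetuses classified by
    their majority hand (ties excluded).
    """
    df = cohort.to_frame()
    sub = df[(df.handedness == group) & (df.gw == gw)]
    if len(sub) == 0:
        raise DegenerateDataError(f"no movements for group={group!r} at gw={gw}")
    prop = float((sub.hand == "right").mean())
    if unit == "movements":
        k, n = int((sub.hand == "right").sum()), len(sub)
    elif unit == "fetuses":
        per_fetus = sub.groupby("fetus_id")["hand"].agg(lambda h: (h == "right").mean())
        per_fetus = per_fetus[per_fetus != 0.5]
        if len(per_fetus) == 0:
            raise DegenerateDataError("no fetus with a majority hand")
        k, n = int((per_fetus > 0.5).sum()), len(per_fetus)
    else:
        raise ValidationError(f"unknown unit {unit!r}")
    return prop, binomial_test(k, n, 0.5)


def rh_use_proportion_from_counts(counts: CountsTable, group: str, gw: int):
    """Same as :func:`rh_use_proportion` but from a counts table (movement unit)."""
    k = counts.cell(group, gw, "right")
    n = counts.column_total(group, gw)
    if n == 0:
        raise DegenerateDataError(f"no movements for group={group!r} at gw={gw}")
    return k / n, binomial_test(k, n, 0.5)


def total_movements_by_fetus(cohort: Cohort) -> TotalsComparison:
    """Per-fetus totals, group mean/SD, and a rank-sum test between groups."""
    tallies = {f.fetus_id: 0 for f in cohort.fetuses}
    for r in cohort.records:
        tallies[r.fetus_id] += 1
    groups = {}
    for g in ("right", "left"):
        ids = cohort.group_ids(g)
        if not ids:
            raise ValidationError(f"no fetuses in group {g!r}")
        groups[g] = np.array([tallies[i] for i in ids], dtype=float)
    res = wilcoxon_rank_sum(groups["right"], groups["left"])
    return TotalsComparison(
        totals=tallies,
        group_mean={g: float(v.mean()) for g, v in groups.items()},
        group_sd={g: float(v.std(ddof=1)) if v.size > 1 else float("nan") for g, v in groups.items()},
        result=res,
    )


def condition_group_comparisons(cohort: Cohort, metric: str, q: float = 0.05):
    """Right- vs left-handed group comparison of pooled movements, per condition.

    Movements (not per-fetus means) are pooled within each group for every
    (gw x target x hand) cell; the Hodges-Lehmann estimate (right-handed
    group minus left-handed group) is tested with the Welch U-test, and
    Benjamini-Hochberg is applied across the computed conditions of the
    metric.  Conditions where either group has fewer than two movements are
    skipped with a diagnostic.
    """
    if metric not in ("mt", "tpv"):
        raise ValidationError(f"unknown metric {metric!r}")
    df = cohort.to_frame()
    comparisons: list[ConditionComparison] = []
    for gw, target, hand in iter_conditions(with_hand=True):
        sub = df[(df.gw == gw) & (df.target == target) & (df.hand == hand)]
        rh_vals = sub.loc[sub.handedness == "right", metric].to_numpy()
        lh_vals = sub.loc[sub.handedness == "left", metric].to_numpy()
        if len(rh_vals) < MIN_GROUP_N or len(lh_vals) < MIN_GROUP_N:
            comparisons.append(
                ConditionComparison(
                    gw, target, hand, metric, len(rh_vals), len(lh_vals),
                    result=None, skipped=True,
                    reason=f"insufficient data (right={len(rh_vals)}, left={len(lh_vals)})",
                )
            )
            continue
        res = welch_u_test(rh_vals, lh_vals)
        comparisons.append(
            ConditionComparison(gw, target, hand, metric, len(rh_vals), len(lh_vals), res)
        )

    tested = [i for i, c in enumerate(comparisons) if not c.skipped]
    if tested:
        adj, reject = benjamini_hochberg([comparisons[i].result.p_raw for i in tested], q=q)
        for j, i in enumerate(tested):
            c = comparisons[i]
            comparisons[i] = ConditionComparison(
                c.gw, c.target, c.hand, c.metric, c.n_right_group, c.n_left_group,
                c.result.with_adjusted(adj[j]), significant=bool(reject[j]),
            )
    return comparisons


def within_subject_correlation(
    cohort: Cohort, metric: str, min_fetuses: int = 3
) -> WithinSubjectCorrelation:
    """Pearson r between per-fetus RH and LH means, per (target x week).

    Only fetuses observed with both hands in the condition contribute;
    conditions with fewer than ``min_fetuses`` such fetuses (or degenerate
    constant means) are omitted with a diagnostic.
    """
    if metric not in ("mt", "tpv"):
        raise ValidationError(f"unknown metric {metric!r}")
    df = cohort.to_frame()
    coeffs: dict[tuple[str, int], float] = {}
    ns: dict[tuple[str, int], int] = {}
    skipped: dict[tuple[str, int], str] = {}
    for gw, target in iter_conditions(with_hand=False):
        sub = df[(df.gw == gw) & (df.target == target)]
        means = sub.groupby(["fetus_id", "hand"])[metric].mean().unstack("hand")
        if "right" not in means.columns or "left" not in means.columns:
            skipped[(target, gw)] = "a hand is entirely unobserved"
            continue
        paired = means.dropna(subset=["right", "left"])
        if len(paired) < min_fetuses:
            skipped[(target, gw)] = f"only {len(paired)} fetuses with both hands"
            continue
        try:
            r, _ = pearson(paired["right"].to_numpy(), paired["left"].to_numpy())
        except DegenerateDataError as exc:
            skipped[(target, gw)] = str(exc)
            continue
        coeffs[(target, gw)] = r
        ns[(target, gw)] = len(paired)
    values = np.array(list(coeffs.values()))
    if values.size == 0:
        raise DegenerateDataError("no condition had enough paired fetuses")
    return WithinSubjectCorrelation(
        metric=metric,
        coefficients=coeffs,
        n_fetuses=ns,
        skipped=skipped,
        median=float(np.median(values)),
        range=(float(values.min()), float(values.max())),
    )
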