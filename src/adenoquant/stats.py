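"""Breeding-trial summaries and the study's statistical tests.

Fertility readouts from a continuous 3-month pair-breeding trial
(percent of dams delivering, litter counts and sizes, cumulative pups
per month) together with the two tests used throughout: a two-sided
Mann-Whitney U test (exact by enumeration for small tie-free samples)
and ordinary two-way ANOVA with interaction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rounding import percent_half_up

CONTROL = "control"
ADENOMYOSIS = "adenomyosis"


@dataclass
class LitterEvent:
    """One delivery: month index within the trial and pup counts."""

    month: int
    pups_born: int
    pups_at_weaning: int

    def __post_init__(self) -> None:
        if not 0 <= self.pups_at_weaning <= self.pups_born:
            raise ValueError(
                f"pups_at_weaning must lie in [0, pups_born], got "
                f"{self.pups_at_weaning} of {self.pups_born}"
            )
        if self.month < 1:
            raise ValueError("month index starts at 1")


@dataclass
class BreedingRecord:
    """Per-dam litter history over the breeding trial."""

    dam_id: str
    group: str
    litters: list[LitterEvent] = field(default_factory=list)

    @property
    def delivered(self) -> bool:
        return len(self.litters) > 0


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _group_records(records: Iterable[BreedingRecord], group: str) -> list[BreedingRecord]:
    sel = [r for r in records if r.group == group]
    if not sel:
        raise ValueError(f"no records in group {group!r}")
    return sel


def percent_delivering(records: Iterable[BreedingRecord], group: str) -> float:
    """Percentage of dams in ``group`` with at least one litter (half-up, 2 dp)."""
    sel = _group_records(records, group)
    return percent_half_up(sum(r.delivered for r in sel), len(sel))


def mean_litter_size(
    records: Iterable[BreedingRecord], group: str, at_weaning: bool = True
) -> float:
    """Total pups divided by total litters for the group.

    ``at_weaning=True`` counts only pups alive at weaning (the trial's
    headline litter-size definition); ``False`` counts pups born.
    """
    sel = _group_records(records, group)
    litters = [ev for r in sel for ev in r.litters]
    if not litters:
        return math.nan
    total = sum(ev.pups_at_weaning if at_weaning else ev.pups_born for ev in litters)
    return total / len(litters)


def mean_litters_per_dam(records: Iterable[BreedingRecord], group: str) -> float:
    sel = _group_records(records, group)
    return sum(len(r.litters) for r in sel) / len(sel)


def cumulative_pups(
    records: Iterable[BreedingRecord], n_months: int = 3, at_weaning: bool = True
) -> pd.DataFrame:
    """Per-dam cumulative pup counts at each month of the trial.

    Returns a DataFrame indexed by dam_id with columns ``group`` and
    ``month_1..month_n``; each series is nondecreasing by construction.
    """
    rows = []
    for rec in records:
        cum = 0
        row: dict[str, object] = {"dam_id": rec.dam_id, "group": rec.group}
        by_month: dict[int, int] = {}
        for ev in rec.litters:
            pups = ev.pups_at_weaning if at_weaning else ev.pups_born
            by_month[ev.month] = by_month.get(ev.month, 0) + pups
        for m in range(1, n_months + 1):
            cum += by_month.get(m, 0)
            row[f"month_{m}"] = cum
        rows.append(row)
    return pd.DataFrame(rows).set_index("dam_id")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for sample x: number of (x_i, y_j) pairs with x_i > y_j, ties 1/2."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def _exact_u_distribution(m: int, n: int) -> dict[float, int]:
    """Null distribution of U by full enumeration of the C(m+n, m) label
    assignments over the pooled tie-free sample."""
    dist: dict[float, int] = {}
    for combo in itertools.combinations(range(m + n), m):
        chosen = set(combo)
        # U = sum over x-positions of (number of y-positions below them)
        u = 0
        n_y_below = 0
        for pos in range(m + n):
            if pos in chosen:
                u += n_y_below
            else:
                n_y_below += 1
        dist[u] = dist.get(u, 0) + 1
    return dist


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of label assignments when both samples
    are small (max n <= ``exact_max_n``) and tie-free; otherwise the
    mid-rank U with tie-corrected normal approximation and continuity
    correction. The two-sided exact p doubles the smaller tail
    min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)

    if max(m, n) <= exact_max_n and not has_ties:
        dist = _exact_u_distribution(m, n)
        total = math.comb(m + n, m)
        p_le = sum(c for val, c in dist.items() if val <= u) / total
        p_ge = sum(c for val, c in dist.items() if val >= u) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=u, p_value=p, method="exact")

    # tie-corrected normal approximation with continuity correction
    N = m + n
    mu = m * n / 2.0
    counts = pd.Series(pooled).value_counts().to_numpy()
    tie_term = float(np.sum(counts**3 - counts))
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return TestResult(statistic=u, p_value=1.0, method="tie-corrected-normal")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * (1.0 - _norm_cdf(z)))
    return TestResult(statistic=u, p_value=p, method="tie-corrected-normal")


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------


def two_way_anova(
    values: Sequence[float],
    factor_group: Sequence,
    factor_time: Sequence,
) -> dict[str, TestResult]:
    """Ordinary two-way ANOVA with interaction (sequential sums of squares).

    Used on cumulative pup counts over months; within-dam repeated
    measures are deliberately ignored, mirroring the study's analysis.
    Returns TestResults keyed by ``group``, ``time`` and ``interaction``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "g": [str(v) for v in factor_group],
            "t": [str(v) for v in factor_time],
        }
    )
    if df["g"].nunique() < 2 or df["t"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    model = smf.ols("y ~ C(g) * C(t)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    out: dict[str, TestResult] = {}
    name_map = {"C(g)": "group", "C(t)": "time", "C(g):C(t)": "interaction"}
    for row_name, key in name_map.items():
        ss = float(table.loc[row_name, "sum_sq"])
        F = float(table.loc[row_name, "F"])
        p = float(table.loc[row_name, "PR(>F)"])
        if ss < 1e-12:
            # zero effect: 0/0 under zero residual variance is undefined
            F, p = 0.0, 1.0
        elif math.isnan(p):
            p = 0.0 if math.isinf(F) else 1.0
        out[key] = TestResult(statistic=F, p_value=p, method=f"anova:{key}")
    out["_residual_ss"] = TestResult(  # type: ignore[assignment]
        statistic=float(table.loc["Residual", "sum_sq"]), p_value=1.0, method="residual"
    )
    return out


# ---------------------------------------------------------------------------
# Cohort ledger
# ---------------------------------------------------------------------------


def cohort_ledger_check(
    sizes_by_timepoint: dict[str, Sequence[int]],
    declared: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sum euthanasia group sizes per arm and compare against enrolment.

    ``sizes_by_timepoint`` maps arm name -> group sizes at each
    euthanasia timepoint; ``declared`` optionally maps arm -> declared
    enrolment for a consistency column.
    """
    rows = []
    for arm, sizes in sizes_by_timepoint.items():
        if any(s < 0 for s in sizes):
            raise ValueError("group sizes must be nonnegative")
        total = int(sum(sizes))
        row = {"arm": arm, "total": total}
        if declared is not None and arm in declared:
            row["declared"] = declared[arm]
            row["consistent"] = total == declared[arm]
        rows.append(row)
    return pd.DataFrame(rows).set_index("arm")


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------


def read_breeding_csv(path) -> list[BreedingRecord]:
    """Read dam_id, group, month, pups_born, pups_weaned rows; one row per
    litter, dams without litters appear with empty month fields."""
    df = pd.read_csv(path, comment="#")
    records: dict[str, BreedingRecord] = {}
    for _, row in df.iterrows():
        dam = str(row["dam_id"])
        rec = records.setdefault(dam, BreedingRecord(dam_id=dam, group=str(row["group"])))
        if pd.notna(row.get("month")):
            rec.litters.append(
                LitterEvent(
                    month=int(row["month"]),
                    pups_born=int(row["pups_born"]),
                    pups_at_weaning=int(row["pups_weaned"]),
                )
            )
    return list(records.values())


def breeding_records_to_frame(records: Iterable[BreedingRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        if not rec.litters:
            rows.append(
                {"dam_id": rec.dam_id, "group": rec.group, "month": pd.NA,
                 "pups_born": pd.NA, "pups_weaned": pd.NA}
            )
        for ev in rec.litters:
            rows.append(
                {"dam_id": rec.dam_id, "group": rec.group, "month": ev.month,
                 "pups_born": ev.pups_born, "pups_weaned": ev.pups_at_weaning}
            )
    return pd.DataFrame(rows)
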