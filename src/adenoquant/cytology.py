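"""Estrous-stage calling from vaginal smear cell compositions.

A daily smear is summarised as counts of three cell classes: nucleated
epithelial cells (dominant in proestrus), cornified epithelial cells
(dominant in estrus) and leukocytes (dense in diestrus). Metestrus is
the brief transition in which cornified cells and leukocytes co-occur.
The classifier encodes those qualitative descriptions as a deterministic
rule cascade with configurable thresholds, and window-level metrics
(percent of days per stage, completed cycles in an observation window)
are computed from the resulting call sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

STAGES = ("proestrus", "estrus", "metestrus", "diestrus")

# default rule thresholds; the source descriptions are qualitative, so
# these are exposed for calibration
METESTRUS_MIN_FRACTION = 0.25  # both cornified and leukocyte fractions
DIESTRUS_LEUKOCYTE_FRACTION = 0.60  # "very high density" of leukocytes

_MAJORITY_STAGE = {
    "nucleated": "proestrus",
    "cornified": "estrus",
    "leukocyte": "diestrus",
}


@dataclass(frozen=True)
class SmearObservation:
    day: int
    nucleated: int
    cornified: int
    leukocyte: int

    def __post_init__(self) -> None:
        if min(self.nucleated, self.cornified, self.leukocyte) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.nucleated + self.cornified + self.leukocyte


@dataclass(frozen=True)
class StageCall:
    day: int
    stage: str
    fractions: dict[str, float]
    rule: str


class UncallableSmearError(ValueError):
    """Raised for an all-zero smear (nothing to classify)."""


def classify_stage(
    obs: SmearObservation,
    m_lo: float = METESTRUS_MIN_FRACTION,
    d_hi: float = DIESTRUS_LEUKOCYTE_FRACTION,
) -> StageCall:
    """Call the estrous stage of one smear.

    Rule precedence: (1) metestrus when cornified and leukocyte
    fractions are both >= ``m_lo`` (the co-occurrence signature);
    (2) diestrus when the leukocyte fraction >= ``d_hi``; (3) otherwise
    the majority cell type decides (nucleated -> proestrus, cornified ->
    estrus, leukocyte -> diestrus), ties broken in that listed order.
    """
    total = obs.total
    if total == 0:
        raise UncallableSmearError(f"day {obs.day}: all-zero smear")
    f = {
        "nucleated": obs.nucleated / total,
        "cornified": obs.cornified / total,
        "leukocyte": obs.leukocyte / total,
    }
    if f["cornified"] >= m_lo and f["leukocyte"] >= m_lo:
        return StageCall(obs.day, "metestrus", f, "cornified+leukocyte")
    if f["leukocyte"] >= d_hi:
        return StageCall(obs.day, "diestrus", f, "leukocyte-density")
    majority = max(("nucleated", "cornified", "leukocyte"), key=lambda k: f[k])
    return StageCall(obs.day, _MAJORITY_STAGE[majority], f, "majority")


def stage_percentages(calls: Sequence[StageCall | None]) -> dict[str, Fraction]:
    """Percent of called days spent in each stage (gaps excluded).

    Values are exact rationals (they sum to 100 exactly); convert to
    float only at formatting time.
    """
    called = [c for c in calls if c is not None]
    if not called:
        raise ValueError("no called days in the window")
    n = len(called)
    out: dict[str, Fraction] = {}
    for stage in STAGES:
        k = sum(c.stage == stage for c in called)
        out[stage] = Fraction(100 * k, n)
    return out


def count_cycles(calls: Sequence[StageCall | None]) -> int:
    """Completed estrous cycles in a window of daily calls.

    A cycle is counted at each entry into estrus — an estrus day whose
    previous *called* day is not estrus — provided at least one
    metestrus-or-diestrus day occurs before the next estrus entry.
    Gaps (None, e.g. failed smears) neither create an entry nor break a
    completion. The window's printed definition ("number of cycles in 14
    days") is operationalised by this scan.
    """
    stages = [c.stage if c is not None else None for c in calls]
    if len(stages) < 2:
        return 0
    completed = 0
    prev_called: str | None = None
    awaiting_completion = False
    for s in stages:
        if s is None:
            continue
        if s == "estrus" and prev_called != "estrus":
            # a new estrus entry: the previous pending cycle (if any)
            # never completed, so it is discarded
            awaiting_completion = True
        elif awaiting_completion and s in ("metestrus", "diestrus"):
            completed += 1
            awaiting_completion = False
        prev_called = s
    return completed


def call_series(
    observations: Iterable[SmearObservation],
    m_lo: float = METESTRUS_MIN_FRACTION,
    d_hi: float = DIESTRUS_LEUKOCYTE_FRACTION,
) -> list[StageCall | None]:
    """Classify a day-ordered series; uncallable smears become gaps."""
    calls: list[StageCall | None] = []
    for obs in sorted(observations, key=lambda o: o.day):
        try:
            calls.append(classify_stage(obs, m_lo=m_lo, d_hi=d_hi))
        except UncallableSmearError:
            calls.append(None)
    return calls


def read_smears_csv(path) -> dict[str, list[SmearObservation]]:
    """Read mouse_id, day, n_nucleated, n_cornified, n_leukocyte."""
    df = pd.read_csv(path, comment="#")
    out: dict[str, list[SmearObservation]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["mouse_id"]), []).append(
            SmearObservation(
                day=int(row["day"]),
                nucleated=int(row["n_nucleated"]),
                cornified=int(row["n_cornified"]),
                leukocyte=int(row["n_leukocyte"]),
            )
        )
    return out


def summarize_mice(
    smears_by_mouse: dict[str, list[SmearObservation]],
    m_lo: float = METESTRUS_MIN_FRACTION,
    d_hi: float = DIESTRUS_LEUKOCYTE_FRACTION,
) -> pd.DataFrame:
    """Per-mouse cyclicity metrics: completed cycles and % days per stage."""
    rows = []
    for mouse_id, obs in smears_by_mouse.items():
        calls = call_series(obs, m_lo=m_lo, d_hi=d_hi)
        pct = stage_percentages(calls)
        rows.append(
            {
                "mouse_id": mouse_id,
                "n_days": len(calls),
                "cycles": count_cycles(calls),
                **{f"pct_{s}": float(pct[s]) for s in STAGES},
            }
        )
    return pd.DataFrame(rows)
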