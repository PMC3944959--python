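"""EQ-5D-3L health states, utility scoring, and visual-acuity conversion.

The EQ-5D-3L instrument describes health on five dimensions (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression), each at
three levels, giving 243 distinct states. A population value set (tariff)
maps each state to a single utility on a scale where 1 is full health and
0 is dead; severe states may score below 0.

The scoring model is the standard additive ("N3-type") form:

    u = full_health
        - any_problem * 1[any dimension > 1]
        - sum of per-dimension decrements for levels 2/3
        - level3_anywhere * 1[any dimension = 3]

The Zimbabwean tariff used in the Zambian study is not published alongside
it, so coefficients are a configuration input; :func:`toy_value_set`
provides a documented synthetic tariff for tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

__all__ = [
    "DIMENSIONS",
    "EQ5DResponse",
    "ValueSet",
    "UtilitySummary",
    "toy_value_set",
    "score_eq5d",
    "all_states",
    "summarize_utilities",
    "paired_utility_change",
    "snellen_to_logmar",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

COUNTING_FINGERS_LOGMAR = 1.85
HAND_MOVEMENTS_LOGMAR = 2.3


@dataclass(frozen=True)
class EQ5DResponse:
    """One EQ-5D-3L response: five dimensions, each level 1 (no problems),
    2 (some problems) or 3 (severe problems)."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise ValueError(
                    f"{dim} level must be 1, 2 or 3; got {level!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)

    @classmethod
    def from_state(cls, state: str | tuple) -> "EQ5DResponse":
        """Build from a 5-digit state label like ``"21111"``."""
        digits = [int(c) for c in state] if isinstance(state, str) else list(state)
        if len(digits) != 5:
            raise ValueError(f"state must have 5 levels, got {state!r}")
        return cls(*digits)


@dataclass(frozen=True)
class ValueSet:
    """Additive tariff mapping an EQ-5D-3L state to a utility.

    ``decrements[dim]`` holds the (level-2, level-3) decrements for each
    dimension; ``any_problem`` is deducted once if any dimension exceeds
    level 1 and ``level3_anywhere`` once if any dimension is at level 3.
    """

    full_health: float = 1.0
    any_problem: float = 0.0
    decrements: dict[str, tuple[float, float]] = field(default_factory=dict)
    level3_anywhere: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.decrements) - set(DIMENSIONS)
        if unknown:
            raise ValueError(f"unknown dimensions in value set: {sorted(unknown)}")
        if self.any_problem < 0 or self.level3_anywhere < 0:
            raise ValueError("value-set constants must be >= 0")
        for dim, (d2, d3) in self.decrements.items():
            if d2 < 0 or d3 < 0:
                raise ValueError(f"negative decrement for {dim}")

    def decrement(self, dim: str, level: int) -> float:
        d2, d3 = self.decrements.get(dim, (0.0, 0.0))
        return {1: 0.0, 2: d2, 3: d3}[level]


def toy_value_set() -> ValueSet:
    """Synthetic tariff for tests: any-problem constant 0.05, every
    level-2 decrement 0.04, every level-3 decrement 0.10, and an extra
    0.10 once any dimension reaches level 3."""
    return ValueSet(
        full_health=1.0,
        any_problem=0.05,
        decrements={dim: (0.04, 0.10) for dim in DIMENSIONS},
        level3_anywhere=0.10,
    )


def score_eq5d(response: EQ5DResponse, vs: ValueSet) -> float:
    """Utility of an EQ-5D-3L state under an additive value set.

    Full health (11111) scores ``vs.full_health`` exactly; severe states
    may score below zero.
    """
    levels = response.levels
    u = vs.full_health
    if any(l > 1 for l in levels):
        u -= vs.any_problem
    for dim, level in zip(DIMENSIONS, levels):
        u -= vs.decrement(dim, level)
    if any(l == 3 for l in levels):
        u -= vs.level3_anywhere
    return u


def all_states() -> list[EQ5DResponse]:
    """All 243 EQ-5D-3L states in lexicographic order."""
    return [EQ5DResponse(*lv) for lv in product((1, 2, 3), repeat=5)]


@dataclass(frozen=True)
class UtilitySummary:
    """Cohort utility summary: n, mean, sample SD, min, max."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    sd_defined: bool = True


def summarize_utilities(values) -> UtilitySummary:
    """Summarise a cohort's utilities (mean, sample SD with ddof=1, range).

    With a single observation the sample SD is undefined; it is reported
    as 0 with ``sd_defined=False``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty utility list")
    sd_defined = arr.size > 1
    return UtilitySummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if sd_defined else 0.0,
        min=float(arr.min()),
        max=float(arr.max()),
        sd_defined=sd_defined,
    )


def paired_utility_change(baseline, followup) -> tuple[float, float]:
    """Mean paired utility change and two-sided paired t-test p-value.

    Returns ``(mean(followup - baseline), p)``. Identical vectors give
    (0.0, 1.0). When every pair changes by the same non-zero amount the t
    statistic degenerates (zero variance of differences); by convention
    the p-value is reported as 0.0.
    """
    b = np.asarray(list(baseline), dtype=float)
    f = np.asarray(list(followup), dtype=float)
    if b.shape != f.shape:
        raise ValueError(
            f"paired vectors differ in length: {b.size} vs {f.size}"
        )
    if b.size < 2:
        raise ValueError("paired comparison needs n >= 2")
    diff = f - b
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        p = 1.0 if mean_diff == 0.0 else 0.0
    else:
        p = float(stats.ttest_rel(f, b).pvalue)
    return mean_diff, p


def snellen_to_logmar(measurement: str | float) -> float:
    """Convert a Snellen acuity or a low-vision category to logMAR.

    Fractions like ``"6/60"`` map to ``log10(denominator/numerator)``;
    the categories "counting fingers" and "hand movements" (or less) map
    to 1.85 and 2.3 logMAR respectively.
    """
    if isinstance(measurement, str):
        text = measurement.strip().lower()
        if text in {"cf", "counting fingers"}:
            return COUNTING_FINGERS_LOGMAR
        if text in {
            "hm",
            "hand movements",
            "hand movements or less",
            "light perception",
            "no light perception",
        }:
            return HAND_MOVEMENTS_LOGMAR
        if "/" in text:
            num_s, _, den_s = text.partition("/")
            try:
                num, den = float(num_s), float(den_s)
            except ValueError:
                raise ValueError(f"unparseable Snellen fraction {measurement!r}")
            if num <= 0 or den <= 0:
                raise ValueError(f"Snellen fraction must be positive: {measurement!r}")
            return float(np.log10(den / num))
        raise ValueError(f"unparseable visual-acuity measurement {measurement!r}")
    raise ValueError(
        f"expected a Snellen string or category, got {type(measurement).__name__}"
    )
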