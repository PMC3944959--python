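"""Life tables and discounted survival annuities.

A life table here is the minimal object a cohort state-transition model
needs: for every integer age, the annual probability ``qx`` of dying from
all causes within the year. The module loads single-year or abridged
(5-year band) tables, synthesises Gompertz-shaped tables when no national
table is available, and computes the discounted, survival-weighted
life-year annuity that converts a constant utility into discounted QALYs.

Conventions
-----------
* Ages are integer years; tables are expanded/padded to a terminal age
  (default 100) whose ``qx`` is 1, closing the cohort.
* Survival treats death as occurring by cycle end:
  ``S(t) = prod_{k=0..t-1} (1 - qx(age0 + k))``, and utility accrues only
  to survivors of the cycle. No half-cycle correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "load_life_table",
    "flat_life_table",
    "synthetic_life_table",
    "discounted_life_annuity",
    "calibrate_flat_mortality",
]

DEFAULT_TERMINAL_AGE = 100


class LifeTableError(ValueError):
    """Raised when a life table fails validation."""


@dataclass(frozen=True)
class LifeTable:
    """Single-year life table: ages and annual death probabilities.

    Parameters
    ----------
    ages
        Consecutive integer ages, strictly increasing with step 1.
    qx
        Annual probability of death within the year, one per age, in
        [0, 1]; the terminal entry is 1 so the cohort closes.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.size == 0:
            raise LifeTableError("empty life table")
        if ages.shape != qx.shape:
            raise LifeTableError("ages and qx must have equal length")
        steps = np.diff(ages)
        if np.any(steps <= 0):
            row = int(np.argmax(steps <= 0)) + 1
            raise LifeTableError(f"ages not strictly increasing at row {row}")
        if np.any(steps != 1):
            row = int(np.argmax(steps != 1)) + 1
            raise LifeTableError(f"age step is not 1 year at row {row}")
        bad = (qx < 0) | (qx > 1)
        if np.any(bad):
            row = int(np.argmax(bad))
            raise LifeTableError(
                f"qx={qx[row]} outside [0, 1] at row {row} (age {ages[row]})"
            )
        if qx[-1] != 1.0:
            raise LifeTableError(
                f"terminal qx must be 1 (got {qx[-1]} at age {ages[-1]}); "
                "normalise via pad_to_terminal()"
            )

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def qx_at(self, age: int) -> float:
        """Annual death probability at an integer ``age``."""
        if age < self.ages[0] or age > self.terminal_age:
            raise LifeTableError(
                f"age {age} outside table range "
                f"[{self.ages[0]}, {self.terminal_age}]"
            )
        return float(self.qx[age - int(self.ages[0])])

    def qx_path(self, start_age: int, n_cycles: int) -> np.ndarray:
        """qx for cycles 1..n starting at ``start_age`` (ages beyond the
        terminal age carry qx = 1)."""
        if start_age < self.ages[0] or start_age > self.terminal_age:
            raise LifeTableError(
                f"start_age {start_age} outside table range "
                f"[{self.ages[0]}, {self.terminal_age}]"
            )
        i0 = start_age - int(self.ages[0])
        path = np.ones(n_cycles, dtype=float)
        avail = min(n_cycles, self.qx.size - i0)
        path[:avail] = self.qx[i0 : i0 + avail]
        return path

    def survival(self, start_age: int, n_cycles: int) -> np.ndarray:
        """S(t) for t = 1..n: probability of surviving t whole cycles."""
        return np.cumprod(1.0 - self.qx_path(start_age, n_cycles))


def _pad_to_terminal(
    ages: np.ndarray, qx: np.ndarray, terminal_age: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend the table to ``terminal_age`` and force terminal qx = 1."""
    last = int(ages[-1])
    if last < terminal_age:
        extra = np.arange(last + 1, terminal_age + 1)
        ages = np.concatenate([ages, extra])
        qx = np.concatenate([qx, np.full(extra.size, qx[-1])])
    qx = qx.copy()
    qx[-1] = 1.0
    return ages, qx


def load_life_table(
    source, terminal_age: int = DEFAULT_TERMINAL_AGE
) -> LifeTable:
    """Load a life table from CSV (path, buffer, or DataFrame).

    Accepted layouts:

    * single-year: columns ``age, qx``;
    * abridged: columns ``age_start, age_end, nqx`` — each band is
      expanded to single years under a constant annual hazard, so the
      annual probability within a band of width ``n`` is
      ``1 - (1 - nqx)**(1/n)`` and the band's n-year survival is
      preserved exactly.

    The result is padded to ``terminal_age`` with the last observed qx
    and the terminal qx is set to 1.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    cols = {c.strip().lower() for c in df.columns}
    df.columns = [c.strip().lower() for c in df.columns]
    if df.empty:
        raise LifeTableError("empty life table")
    if {"age", "qx"} <= cols:
        ages = df["age"].to_numpy(dtype=float)
        if np.any(ages != np.round(ages)):
            row = int(np.argmax(ages != np.round(ages)))
            raise LifeTableError(f"non-integer age at row {row}")
        ages = ages.astype(int)
        qx = df["qx"].to_numpy(dtype=float)
    elif {"age_start", "age_end", "nqx"} <= cols:
        ages_list: list[int] = []
        qx_list: list[float] = []
        for row, rec in enumerate(df.itertuples(index=False)):
            a0, a1, nqx = int(rec.age_start), int(rec.age_end), float(rec.nqx)
            n = a1 - a0 + 1
            if n < 1:
                raise LifeTableError(f"band end before start at row {row}")
            if not 0.0 <= nqx <= 1.0:
                raise LifeTableError(f"nqx={nqx} outside [0, 1] at row {row}")
            annual = 1.0 - (1.0 - nqx) ** (1.0 / n)
            ages_list.extend(range(a0, a1 + 1))
            qx_list.extend([annual] * n)
        ages = np.asarray(ages_list, dtype=int)
        qx = np.asarray(qx_list, dtype=float)
    else:
        raise LifeTableError(
            "life table needs columns (age, qx) or (age_start, age_end, nqx); "
            f"got {sorted(cols)}"
        )
    bad = (qx < 0) | (qx > 1)
    if np.any(bad):
        row = int(np.argmax(bad))
        raise LifeTableError(f"qx={qx[row]} outside [0, 1] at row {row}")
    ages, qx = _pad_to_terminal(ages, qx, max(terminal_age, int(ages[-1])))
    return LifeTable(ages, qx)


def flat_life_table(
    q: float, first_age: int = 0, terminal_age: int = DEFAULT_TERMINAL_AGE
) -> LifeTable:
    """Life table with a constant annual death probability ``q``."""
    if not 0.0 <= q <= 1.0:
        raise LifeTableError(f"q={q} outside [0, 1]")
    ages = np.arange(first_age, terminal_age + 1)
    qx = np.full(ages.size, float(q))
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def synthetic_life_table(
    level: float,
    shape: float,
    max_age: int = DEFAULT_TERMINAL_AGE,
    warn_early_extinction: bool = True,
) -> LifeTable:
    """Gompertz-shaped stand-in table: ``qx = 1 - exp(-level * e^{shape*age})``.

    Deterministic given its parameters. Emits a warning (not an error) if
    the parameters drive qx to 1 before age 40.
    """
    ages = np.arange(0, max_age + 1)
    hazard = level * np.exp(shape * ages.astype(float))
    qx = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    if warn_early_extinction and np.any(qx[ages < 40] >= 1.0):
        import warnings

        warnings.warn(
            "synthetic life table reaches qx=1 before age 40; "
            "check (level, shape)",
            stacklevel=2,
        )
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def discounted_life_annuity(
    lt: LifeTable,
    start_age: int,
    rate: float,
    horizon: int | None = None,
    half_cycle_correction: bool = False,
) -> float:
    """Discounted survival-weighted life years from ``start_age``.

    Returns ``sum_{t=1..H} (1 + rate)^{-t} * S(t)`` where ``S(t)`` is the
    probability of surviving ``t`` whole cycles; ``horizon=None`` means
    lifetime (H runs to the terminal age). With the half-cycle correction
    each term weights the average of start- and end-of-cycle survival.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if start_age > lt.terminal_age:
        raise LifeTableError(
            f"start_age {start_age} beyond terminal age {lt.terminal_age}"
        )
    H = lt.terminal_age - start_age if horizon is None else int(horizon)
    H = max(H, 1) if horizon is None else H
    if H < 1:
        raise ValueError(f"horizon must be >= 1, got {H}")
    t = np.arange(1, H + 1)
    S = lt.survival(start_age, H)
    if half_cycle_correction:
        S_prev = np.concatenate([[1.0], S[:-1]])
        S = 0.5 * (S_prev + S)
    return float(np.sum((1.0 + rate) ** (-t.astype(float)) * S))


def calibrate_flat_mortality(
    target_annuity: float,
    start_age: int,
    rate: float,
    horizon: int | None = None,
    terminal_age: int = DEFAULT_TERMINAL_AGE,
    tol: float = 1e-6,
) -> float:
    """Constant annual death probability whose annuity matches a target.

    Bisection on q in [0, 1]: the annuity is strictly decreasing in q, so
    the root is unique when the target lies between the all-dead (q=1)
    and zero-mortality (q=0) annuities. Used to reproduce a published
    discounted-QALY total when the underlying national life table is not
    available: only the plain annuity is matched, not the age profile.
    """

    def annuity(q: float) -> float:
        return discounted_life_annuity(
            flat_life_table(q, first_age=0, terminal_age=terminal_age),
            start_age,
            rate,
            horizon,
        )

    hi_val = annuity(0.0)  # zero mortality: largest achievable
    lo_val = annuity(1.0)  # immediate extinction: smallest
    if not lo_val <= target_annuity <= hi_val:
        raise ValueError(
            f"target annuity {target_annuity} outside feasible range "
            f"[{lo_val:.6g}, {hi_val:.6g}] for start_age={start_age}, "
            f"rate={rate}"
        )
    lo, hi = 0.0, 1.0  # annuity(lo) = hi_val >= target >= annuity(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if annuity(mid) > target_annuity:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    q = 0.5 * (lo + hi)
    if abs(annuity(q) - target_annuity) > tol:
        raise ValueError(
            f"bisection failed to reach tolerance {tol} for target "
            f"{target_annuity}"
        )
    return q
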