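"""Cohort state-transition (Markov) models for cataract surgery and
refractive-error correction.

Both models share one three-state engine:

* **T** (treated) — post-intervention utility;
* **D** (deteriorated / untreated) — baseline utility until death;
* **M** (dead) — absorbing, utility 0.

The intervention cohort enters 100% in T with the treatment cost charged
once at entry (cycle 0, undiscounted); the comparator cohort enters 100%
in D at zero cost. Each annual cycle t = 1, 2, ...:

1. survivors of the cycle are determined from the life table's qx at the
   age held at the cycle start (death applies equally from T and D);
2. survivors accrue the utility of the state they held during the cycle,
   discounted by (1 + r)^(-t);
3. the T -> D transition is applied at the end of the cycle
   (a constant 4%/year for cataract; a time-varying spectacle-loss
   probability for refraction).

The spectacle-loss schedule rises from 5% at the end of the first cycle
to 90% at the end of the 5-year horizon. The default reading interpolates
geometrically between the two endpoints,
``p(t) = p1 * (pH/p1)^((t-1)/(H-1))``; an alternative reading that treats
the printed endpoints as *cumulative* loss fractions is available behind
``cumulative_schedule=True``.

No half-cycle correction is applied by default (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .life_tables import LifeTable

__all__ = [
    "CataractParams",
    "RefractionParams",
    "CohortTrace",
    "ArmResult",
    "CEResult",
    "Icer",
    "loss_probability",
    "run_arm",
    "run_cataract_model",
    "run_refraction_model",
    "compute_icer",
]


@dataclass(frozen=True)
class CataractParams:
    """Cataract model inputs: lifetime horizon from age 63.

    Defaults are the pooled Zambian study values: surgery cost US$92,
    baseline utility 0.782, post-surgery utility 0.832, 4%/year
    deterioration back to baseline, 3% discounting.
    """

    life_table: LifeTable
    surgery_cost: float = 92.0
    u_base: float = 0.782
    u_post: float = 0.832
    p_deteriorate: float = 0.04
    discount_rate: float = 0.03
    start_age: int = 63
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_deteriorate <= 1.0:
            raise ValueError(f"p_deteriorate outside [0, 1]: {self.p_deteriorate}")
        for name in ("u_base", "u_post"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {u}")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")


@dataclass(frozen=True)
class RefractionParams:
    """Refraction model inputs: 5 annual cycles from age 39.

    Defaults are the pooled study values: spectacles US$72, baseline
    utility 0.850, corrected utility 0.925, spectacle-loss probability
    rising from 5% (cycle 1) to 90% (final cycle), 3% discounting.
    """

    life_table: LifeTable
    spectacles_cost: float = 72.0
    u_base: float = 0.850
    u_post: float = 0.925
    loss_p1: float = 0.05
    loss_pH: float = 0.90
    horizon: int = 5
    discount_rate: float = 0.03
    start_age: int = 39
    cumulative_schedule: bool = False
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.loss_p1 <= self.loss_pH <= 1.0:
            raise ValueError(
                f"need 0 < loss_p1 <= loss_pH <= 1; got "
                f"({self.loss_p1}, {self.loss_pH})"
            )
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")


def loss_probability(cycle: int, params: RefractionParams) -> float:
    """Spectacle-loss probability applied at the end of ``cycle``.

    Geometric interpolation through the two fixed endpoints:
    ``p(t) = p1 * (pH/p1)^((t-1)/(H-1))``, so p(1) = p1 and p(H) = pH.
    Under ``cumulative_schedule`` the same curve is read as the
    *cumulative* fraction lost by the end of cycle t and converted to the
    conditional per-cycle probability.
    """
    H = params.horizon
    if not 1 <= cycle <= H:
        raise ValueError(f"cycle {cycle} outside 1..{H}")
    if H == 1:
        return params.loss_pH

    def curve(t: int) -> float:
        return params.loss_p1 * (params.loss_pH / params.loss_p1) ** (
            (t - 1) / (H - 1)
        )

    if not params.cumulative_schedule:
        return curve(cycle)
    cum_now = curve(cycle)
    cum_prev = curve(cycle - 1) if cycle > 1 else 0.0
    if cum_prev >= 1.0:
        return 1.0
    return (cum_now - cum_prev) / (1.0 - cum_prev)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort ledger for one model arm.

    Row t holds the occupancy of T/D/M *after* cycle t's events and the
    discounted QALY and cost increments accrued during cycle t; row 0 is
    the entry state (entry cost charged there).
    """

    df: pd.DataFrame

    def occupancy(self, state: str) -> np.ndarray:
        return self.df[f"state_{state}"].to_numpy()


@dataclass(frozen=True)
class ArmResult:
    cost: float
    qalys: float
    trace: CohortTrace


@dataclass(frozen=True)
class Icer:
    """Incremental cost-effectiveness ratio with dominance status.

    ``status`` is ``"ratio"`` for a conventional positive ratio,
    ``"dominant"`` when the intervention saves money and gains QALYs,
    ``"dominated"`` when it costs more and loses QALYs, and
    ``"undefined"`` when both increments are zero.
    """

    value: float
    status: str

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class CEResult:
    """Per-patient discounted totals for both arms and their increments."""

    comparator: ArmResult
    intervention: ArmResult

    @property
    def inc_cost(self) -> float:
        return self.intervention.cost - self.comparator.cost

    @property
    def inc_qalys(self) -> float:
        return self.intervention.qalys - self.comparator.qalys

    @property
    def icer(self) -> Icer:
        return compute_icer(self.inc_cost, self.inc_qalys)


def compute_icer(inc_cost: float, inc_qaly: float) -> Icer:
    """Incremental cost per QALY gained, with dominance flags."""
    if inc_qaly > 0:
        status = "dominant" if inc_cost < 0 else "ratio"
        return Icer(inc_cost / inc_qaly, status)
    if inc_qaly == 0 and inc_cost == 0:
        return Icer(float("nan"), "undefined")
    if inc_cost > 0:
        return Icer(float("nan"), "dominated")
    # fewer QALYs for less money (or equal): ratio in the SW quadrant
    return Icer(
        inc_cost / inc_qaly if inc_qaly != 0 else float("inf"),
        "southwest",
    )


def run_arm(
    life_table: LifeTable,
    start_age: int,
    horizon: int,
    u_T,
    u_D,
    p_td: Callable[[int], float] | float,
    discount_rate: float,
    entry_cost,
    start_in_T: bool = True,
    half_cycle_correction: bool = False,
    collect_trace: bool = True,
) -> tuple[np.ndarray, np.ndarray, CohortTrace | None]:
    """Run one cohort arm of the three-state engine.

    Utilities, ``entry_cost`` and (scalar) ``p_td`` may be numpy arrays of
    a common shape, in which case the whole arm is evaluated element-wise
    (used by the probabilistic sensitivity analysis); the trace is only
    collected for scalar runs.

    Returns ``(discounted_cost, discounted_qalys, trace)``.
    """
    u_T = np.asarray(u_T, dtype=float)
    u_D = np.asarray(u_D, dtype=float)
    entry_cost = np.asarray(entry_cost, dtype=float)
    vector = max(u_T.ndim, u_D.ndim, entry_cost.ndim) > 0
    if vector and collect_trace:
        collect_trace = False

    qx = life_table.qx_path(start_age, horizon)
    shape = np.broadcast_shapes(u_T.shape, u_D.shape, entry_cost.shape)
    T = np.ones(shape) if start_in_T else np.zeros(shape)
    D = np.zeros(shape) if start_in_T else np.ones(shape)
    M = np.zeros(shape)
    qalys = np.zeros(shape)
    cost = np.zeros(shape) + entry_cost

    rows = []
    if collect_trace:
        rows.append((0, float(T), float(D), float(M), 0.0, float(entry_cost)))

    for t in range(1, horizon + 1):
        q = qx[t - 1]
        sT, sD = T * (1.0 - q), D * (1.0 - q)
        M = M + (T + D) * q
        disc = (1.0 + discount_rate) ** (-t)
        if half_cycle_correction:
            accrual = 0.5 * ((T + sT) * u_T + (D + sD) * u_D)
        else:
            accrual = sT * u_T + sD * u_D
        dq = disc * accrual
        qalys = qalys + dq
        if callable(p_td):
            p = p_td(t)
        else:
            p = p_td
        T = sT * (1.0 - p)
        D = sD + sT * p
        if collect_trace:
            rows.append((t, float(T), float(D), float(M), float(dq), 0.0))

    trace = None
    if collect_trace:
        trace = CohortTrace(
            pd.DataFrame(
                rows,
                columns=["cycle", "state_T", "state_D", "state_M", "disc_qaly", "disc_cost"],
            )
        )
    return cost, qalys, trace


def _lifetime_horizon(lt: LifeTable, start_age: int) -> int:
    H = lt.terminal_age - start_age + 1
    if H < 1:
        raise ValueError(
            f"life table ends at {lt.terminal_age}, before start age {start_age}"
        )
    return H


def run_cataract_model(params: CataractParams) -> CEResult:
    """Lifetime cataract model: surgery vs no surgery from age 63."""
    H = _lifetime_horizon(params.life_table, params.start_age)
    common = dict(
        life_table=params.life_table,
        start_age=params.start_age,
        horizon=H,
        discount_rate=params.discount_rate,
        half_cycle_correction=params.half_cycle_correction,
    )
    c_cost, c_q, c_tr = run_arm(
        u_T=params.u_post,
        u_D=params.u_base,
        p_td=0.0,
        entry_cost=0.0,
        start_in_T=False,
        **common,
    )
    i_cost, i_q, i_tr = run_arm(
        u_T=params.u_post,
        u_D=params.u_base,
        p_td=params.p_deteriorate,
        entry_cost=params.surgery_cost,
        start_in_T=True,
        **common,
    )
    return CEResult(
        comparator=ArmResult(float(c_cost), float(c_q), c_tr),
        intervention=ArmResult(float(i_cost), float(i_q), i_tr),
    )


def run_refraction_model(params: RefractionParams) -> CEResult:
    """Five-cycle refraction model: spectacles vs none from age 39."""
    common = dict(
        life_table=params.life_table,
        start_age=params.start_age,
        horizon=params.horizon,
        discount_rate=params.discount_rate,
        half_cycle_correction=params.half_cycle_correction,
    )
    c_cost, c_q, c_tr = run_arm(
        u_T=params.u_post,
        u_D=params.u_base,
        p_td=0.0,
        entry_cost=0.0,
        start_in_T=False,
        **common,
    )
    i_cost, i_q, i_tr = run_arm(
        u_T=params.u_post,
        u_D=params.u_base,
        p_td=lambda t: loss_probability(t, params),
        entry_cost=params.spectacles_cost,
        start_in_T=True,
        **common,
    )
    return CEResult(
        comparator=ArmResult(float(c_cost), float(c_q), c_tr),
        intervention=ArmResult(float(i_cost), float(i_q), i_tr),
    )


def with_params(params, **updates):
    """Frozen-dataclass update helper (used by the PSA and sensitivity runs)."""
    return replace(params, **updates)
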