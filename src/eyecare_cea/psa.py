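"""Probabilistic sensitivity analysis (PSA) and cost-effectiveness
acceptability curves (CEAC).

Parameter uncertainty is propagated by Monte Carlo: each uncertain input
gets a distribution parameterised from its reported mean and standard
error by the method of moments — beta for utilities and transition
probabilities, gamma for costs — every iteration draws all parameters
independently, runs the deterministic cohort model, and records the
incremental cost and QALYs. The CEAC reports, for each willingness-to-pay
threshold λ, the fraction of iterations whose incremental net monetary
benefit λ·ΔQALY − ΔCost is positive.

Reproducibility contract: one ``numpy.random.default_rng(seed)`` stream
per run; parameters are drawn in a fixed documented order (cost, baseline
utility, post-treatment utility, transition probability), each as a
length-``n_iter`` vector, so identical (seed, n_iter, config) gives
bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CataractParams, RefractionParams, compute_icer, run_arm

__all__ = [
    "GNI_THRESHOLD_USD",
    "ParamDistribution",
    "PSAResult",
    "CEAC",
    "beta_from_moments",
    "gamma_from_moments",
    "run_cataract_psa",
    "run_refraction_psa",
    "ceac",
    "probability_cost_effective",
    "summarize_psa",
    "default_threshold_grid",
]

#: 2011 Zambian gross national income per capita, the willingness-to-pay
#: benchmark under which an intervention counts as highly cost-effective.
GNI_THRESHOLD_USD = 1160.0


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(α, β) shape parameters matching a mean and standard error.

    Method of moments: ν = mean(1−mean)/se² − 1, α = mean·ν,
    β = (1−mean)·ν. Feasible only when 0 < se² < mean(1−mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    var = se * se
    bound = mean * (1.0 - mean)
    if not 0.0 < var < bound:
        raise ValueError(
            f"beta se infeasible: need 0 < se^2 < mean*(1-mean) = {bound:.6g}, "
            f"got se^2 = {var:.6g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard error:
    shape = (mean/se)², scale = se²/mean."""
    if mean <= 0 or se <= 0:
        raise ValueError(f"gamma needs mean > 0 and se > 0, got ({mean}, {se})")
    return (mean / se) ** 2, se * se / mean


@dataclass(frozen=True)
class ParamDistribution:
    """An uncertain model input: name, family (beta/gamma/fixed), mean, se.

    ``fixed`` pins the parameter at its mean (se ignored); the other
    families are parameterised by the method of moments at draw time, so
    infeasible (mean, se) pairs fail before any iteration runs.
    """

    name: str
    family: str
    mean: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "beta":
            beta_from_moments(self.mean, self.se)
        elif self.family == "gamma":
            gamma_from_moments(self.mean, self.se)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "beta":
            a, b = beta_from_moments(self.mean, self.se)
            return rng.beta(a, b, size=n)
        shape, scale = gamma_from_moments(self.mean, self.se)
        return rng.gamma(shape, scale, size=n)


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo PSA output: per-iteration parameter draws and per-arm
    discounted costs/QALYs, plus the increments the CEAC needs."""

    draws: pd.DataFrame  # one row per iteration: params, arm totals, increments
    n_iter: int
    seed: int
    intervention: str

    @property
    def inc_cost(self) -> np.ndarray:
        return self.draws["inc_cost"].to_numpy()

    @property
    def inc_qaly(self) -> np.ndarray:
        return self.draws["inc_qaly"].to_numpy()


@dataclass(frozen=True)
class CEAC:
    """Probability cost-effective as a function of willingness to pay."""

    thresholds: np.ndarray
    probability: np.ndarray

    def at(self, threshold: float) -> float:
        idx = np.nonzero(np.isclose(self.thresholds, threshold))[0]
        if idx.size == 0:
            raise ValueError(f"threshold {threshold} not on the grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "p_cost_effective": self.probability}
        )


def default_threshold_grid() -> np.ndarray:
    """US$0–2,000/QALY in steps of 10, always including the GNI benchmark."""
    grid = np.arange(0.0, 2000.0 + 10.0, 10.0)
    if not np.any(np.isclose(grid, GNI_THRESHOLD_USD)):
        grid = np.sort(np.append(grid, GNI_THRESHOLD_USD))
    return grid


def _dist(name, family, mean, se, overrides) -> ParamDistribution:
    if overrides and name in overrides:
        return overrides[name]
    return ParamDistribution(name, family, mean, se)


def run_cataract_psa(
    params: CataractParams,
    n_iter: int = 10_000,
    seed: int = 0,
    se: dict[str, float] | None = None,
    distributions: dict[str, ParamDistribution] | None = None,
) -> PSAResult:
    """PSA over the cataract model.

    Uncertain inputs and default SEs (overridable via ``se`` or full
    ``distributions``): cost ~ gamma(92, 3.4); baseline utility ~
    beta(0.782, 0.017); post-surgery utility ~ beta(0.832, 0.015);
    deterioration probability ~ beta(0.04, 0.01). Draw order is fixed:
    cost, u_base, u_post, p_deteriorate.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    se = {"cost": 3.4, "u_base": 0.017, "u_post": 0.015, "p_deteriorate": 0.01} | (
        se or {}
    )
    dists = [
        _dist("cost", "gamma", params.surgery_cost, se["cost"], distributions),
        _dist("u_base", "beta", params.u_base, se["u_base"], distributions),
        _dist("u_post", "beta", params.u_post, se["u_post"], distributions),
        _dist(
            "p_deteriorate",
            "beta",
            params.p_deteriorate,
            se["p_deteriorate"],
            distributions,
        ),
    ]
    rng = np.random.default_rng(seed)
    draws = {d.name: d.sample(rng, n_iter) for d in dists}

    H = params.life_table.terminal_age - params.start_age + 1
    common = dict(
        life_table=params.life_table,
        start_age=params.start_age,
        horizon=H,
        discount_rate=params.discount_rate,
        half_cycle_correction=params.half_cycle_correction,
        collect_trace=False,
    )
    c_cost, c_q, _ = run_arm(
        u_T=draws["u_post"],
        u_D=draws["u_base"],
        p_td=0.0,
        entry_cost=np.zeros(n_iter),
        start_in_T=False,
        **common,
    )
    i_cost, i_q, _ = run_arm(
        u_T=draws["u_post"],
        u_D=draws["u_base"],
        p_td=draws["p_deteriorate"],
        entry_cost=draws["cost"],
        start_in_T=True,
        **common,
    )
    return _package_result(
        draws, c_cost, c_q, i_cost, i_q, n_iter, seed, "cataract"
    )


def run_refraction_psa(
    params: RefractionParams,
    n_iter: int = 10_000,
    seed: int = 0,
    se: dict[str, float] | None = None,
    distributions: dict[str, ParamDistribution] | None = None,
) -> PSAResult:
    """PSA over the refraction model.

    Uncertain inputs and default SEs: cost ~ gamma(72, 7.8); baseline
    utility ~ beta(0.850, 0.022); corrected utility ~ beta(0.925, 0.018);
    first-cycle spectacle-loss probability ~ beta(0.05, 0.01). Only the
    first-cycle loss probability carries a reported SE, so each iteration
    rescales the geometric schedule through its drawn ``loss_p1`` while
    keeping the final-cycle value pinned at ``loss_pH``. Draw order:
    cost, u_base, u_post, loss_p1.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    se = {"cost": 7.8, "u_base": 0.022, "u_post": 0.018, "loss_p1": 0.01} | (
        se or {}
    )
    dists = [
        _dist("cost", "gamma", params.spectacles_cost, se["cost"], distributions),
        _dist("u_base", "beta", params.u_base, se["u_base"], distributions),
        _dist("u_post", "beta", params.u_post, se["u_post"], distributions),
        _dist("loss_p1", "beta", params.loss_p1, se["loss_p1"], distributions),
    ]
    rng = np.random.default_rng(seed)
    draws = {d.name: d.sample(rng, n_iter) for d in dists}

    common = dict(
        life_table=params.life_table,
        start_age=params.start_age,
        horizon=params.horizon,
        discount_rate=params.discount_rate,
        half_cycle_correction=params.half_cycle_correction,
        collect_trace=False,
    )

    p1 = draws["loss_p1"]

    def p_loss(t: int) -> np.ndarray:
        # vectorised geometric schedule per iteration, endpoint pinned
        H = params.horizon
        if H == 1:
            return np.full_like(p1, params.loss_pH)
        frac = (t - 1) / (H - 1)
        if not params.cumulative_schedule:
            return p1 * (params.loss_pH / p1) ** frac

        def curve(tt):
            return p1 * (params.loss_pH / p1) ** ((tt - 1) / (H - 1))

        cum_now = curve(t)
        cum_prev = curve(t - 1) if t > 1 else np.zeros_like(p1)
        return np.where(
            cum_prev >= 1.0, 1.0, (cum_now - cum_prev) / (1.0 - cum_prev)
        )

    c_cost, c_q, _ = run_arm(
        u_T=draws["u_post"],
        u_D=draws["u_base"],
        p_td=0.0,
        entry_cost=np.zeros(n_iter),
        start_in_T=False,
        **common,
    )
    i_cost, i_q, _ = run_arm(
        u_T=draws["u_post"],
        u_D=draws["u_base"],
        p_td=p_loss,
        entry_cost=draws["cost"],
        start_in_T=True,
        **common,
    )
    return _package_result(
        draws, c_cost, c_q, i_cost, i_q, n_iter, seed, "refraction"
    )


def _package_result(
    draws, c_cost, c_q, i_cost, i_q, n_iter, seed, intervention
) -> PSAResult:
    df = pd.DataFrame(draws)
    df["comparator_cost"] = np.broadcast_to(c_cost, (n_iter,))
    df["comparator_qalys"] = c_q
    df["intervention_cost"] = i_cost
    df["intervention_qalys"] = i_q
    df["inc_cost"] = i_cost - c_cost
    df["inc_qaly"] = i_q - c_q
    df.insert(0, "iteration", np.arange(1, n_iter + 1))
    if not np.all(np.isfinite(df.drop(columns=["iteration"]).to_numpy())):
        raise FloatingPointError("non-finite values in PSA result")
    return PSAResult(draws=df, n_iter=n_iter, seed=seed, intervention=intervention)


def ceac(result: PSAResult, thresholds=None) -> CEAC:
    """Probability cost-effective across a willingness-to-pay grid.

    At each λ, the fraction of iterations with net monetary benefit
    λ·ΔQALY − ΔCost > 0.
    """
    grid = default_threshold_grid() if thresholds is None else np.asarray(
        list(np.atleast_1d(thresholds)), dtype=float
    )
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    dq = result.inc_qaly[None, :]
    dc = result.inc_cost[None, :]
    nmb = grid[:, None] * dq - dc
    prob = (nmb > 0).mean(axis=1)
    return CEAC(thresholds=grid, probability=prob)


def probability_cost_effective(
    result: PSAResult, threshold: float = GNI_THRESHOLD_USD
) -> float:
    """Fraction of iterations cost-effective at a single threshold."""
    nmb = threshold * result.inc_qaly - result.inc_cost
    return float((nmb > 0).mean())


def summarize_psa(result: PSAResult, mean_of_ratios: bool = False) -> dict:
    """Probabilistic summary row: per-arm mean costs/QALYs, mean
    increments, and the ICER as the ratio of mean increments (default) or
    the mean of per-iteration ratios (``mean_of_ratios=True``)."""
    df = result.draws
    out = {
        "intervention": result.intervention,
        "n_iter": result.n_iter,
        "seed": result.seed,
        "comparator_cost": float(df["comparator_cost"].mean()),
        "comparator_qalys": float(df["comparator_qalys"].mean()),
        "intervention_cost": float(df["intervention_cost"].mean()),
        "intervention_qalys": float(df["intervention_qalys"].mean()),
        "inc_cost": float(df["inc_cost"].mean()),
        "inc_qaly": float(df["inc_qaly"].mean()),
    }
    if mean_of_ratios:
        ratios = df["inc_cost"] / df["inc_qaly"]
        out["icer"] = float(ratios.mean())
        out["icer_method"] = "mean_of_ratios"
    else:
        icer = compute_icer(out["inc_cost"], out["inc_qaly"])
        out["icer"] = icer.value
        out["icer_method"] = "ratio_of_means"
        out["icer_status"] = icer.status
    out["p_cost_effective_at_gni"] = probability_cost_effective(result)
    return out
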