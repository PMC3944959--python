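"""Synthetic patient-level cohorts.

The underlying patient records of the Zambian cohort study are not
deposited, so this module generates statistically matched stand-ins:
baseline EQ-5D utilities drawn from a beta distribution fitted by moments
to the published cohort mean/SD, follow-up utilities as baseline plus an
independent treatment-effect draw clipped at the EQ-5D ceiling of 1 (the
raw shift is calibrated so the realised post-ceiling mean change matches
the target effect), and
per-patient cost components drawn from gamma distributions around the
published facility means. Every draw is reproducible under a seed.

What the generator does *not* emulate: baseline–follow-up correlation
(none is reported), socio-demographic covariates beyond group size, and
visual acuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .psa import beta_from_moments, gamma_from_moments

__all__ = ["CohortSpec", "generate_cohort", "recover_parameters"]


@dataclass(frozen=True)
class CohortSpec:
    """Target moments for a synthetic patient cohort.

    Defaults mirror the published cataract cohort: n = 77, baseline
    utility 0.782 (SD 0.150), mean treatment effect 0.05 with an assumed
    SD of individual changes of 0.17 (consistent with the observed
    baseline/follow-up SDs).
    """

    n_patients: int = 77
    baseline_mean: float = 0.782
    baseline_sd: float = 0.150
    effect_mean: float = 0.05
    change_sd: float = 0.17
    cost_means: dict[str, float] = field(default_factory=dict)
    cost_cv: float = 0.3  # coefficient of variation of cost draws
    loss_to_followup: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 < self.baseline_mean < 1.0:
            raise ValueError("baseline_mean must lie in (0, 1)")
        if self.baseline_sd < 0 or self.change_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.loss_to_followup < 1.0:
            raise ValueError("loss_to_followup must lie in [0, 1)")
        if self.baseline_sd > 0:
            # fail fast on infeasible beta moments
            beta_from_moments(self.baseline_mean, self.baseline_sd)


def _expected_clipped_change(
    mu: float, sigma: float, beta_ab: tuple[float, float] | float
) -> float:
    """E[min(b + c, 1) - b] for c ~ N(mu, sigma) and b ~ Beta (or a point
    mass), using the censored-normal mean for each baseline value."""

    def clipped_mean(x: float) -> float:
        m = x + mu
        if sigma == 0:
            return min(m, 1.0)
        z = (m - 1.0) / sigma
        return m - (m - 1.0) * stats.norm.cdf(z) - sigma * stats.norm.pdf(z)

    if isinstance(beta_ab, tuple):
        a, b = beta_ab
        pdf = stats.beta(a, b).pdf
        val, _ = integrate.quad(
            lambda x: pdf(x) * (clipped_mean(x) - x), 0.0, 1.0, limit=200
        )
        return val
    return clipped_mean(beta_ab) - beta_ab


def _calibrate_effect_shift(spec: CohortSpec) -> float:
    """Raw mean shift whose post-ceiling realised mean change equals
    ``spec.effect_mean``.

    Clipping follow-up utilities at the EQ-5D ceiling of 1 pulls the
    realised mean change below the raw shift, so the shift is solved for
    numerically; infeasible targets (beyond the headroom E[1 - baseline])
    fail with the feasible bound.
    """
    if spec.effect_mean == 0.0 and spec.change_sd == 0.0:
        return 0.0
    beta_ab: tuple[float, float] | float
    if spec.baseline_sd == 0:
        beta_ab = spec.baseline_mean
    else:
        beta_ab = beta_from_moments(spec.baseline_mean, spec.baseline_sd)

    def gap(mu: float) -> float:
        return _expected_clipped_change(mu, spec.change_sd, beta_ab) - spec.effect_mean

    hi = 1.0
    if gap(hi) < 0:
        headroom = _expected_clipped_change(100.0, spec.change_sd, beta_ab)
        raise ValueError(
            f"effect_mean {spec.effect_mean} exceeds the ceiling headroom "
            f"(max realised mean change ~{headroom:.3f})"
        )
    lo = min(spec.effect_mean - 5 * spec.change_sd, 0.0) - 1.0
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one patient-level cohort as a DataFrame.

    Columns: ``patient_id``, ``baseline_utility``, ``followup_utility``
    (NaN for patients lost to follow-up), plus one ``cost_<category>``
    column per entry of ``spec.cost_means``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    if spec.baseline_sd == 0:
        baseline = np.full(n, spec.baseline_mean)
    else:
        a, b = beta_from_moments(spec.baseline_mean, spec.baseline_sd)
        baseline = rng.beta(a, b, size=n)

    raw_shift = _calibrate_effect_shift(spec)
    if spec.change_sd == 0:
        change = np.full(n, raw_shift)
    else:
        change = rng.normal(raw_shift, spec.change_sd, size=n)
    followup = np.minimum(baseline + change, 1.0)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "baseline_utility": baseline,
            "followup_utility": followup,
        }
    )
    for category, mean in spec.cost_means.items():
        if mean < 0:
            raise ValueError(f"cost mean for {category!r} must be >= 0")
        if mean == 0 or spec.cost_cv == 0:
            df[f"cost_{category}"] = mean
        else:
            shape, scale = gamma_from_moments(mean, spec.cost_cv * mean)
            df[f"cost_{category}"] = rng.gamma(shape, scale, size=n)

    if spec.loss_to_followup > 0:
        lost = rng.random(n) < spec.loss_to_followup
        df.loc[lost, "followup_utility"] = np.nan
    return df


def recover_parameters(records: pd.DataFrame) -> dict:
    """Sample moments of a generated cohort, for closed-loop recovery.

    Returns baseline mean/SD, mean change and its SD over patients with
    follow-up, and per-category cost means.
    """
    if len(records) < 2:
        raise ValueError("parameter recovery needs n >= 2")
    baseline = records["baseline_utility"].to_numpy(dtype=float)
    followed = records.dropna(subset=["followup_utility"])
    change = (
        followed["followup_utility"] - followed["baseline_utility"]
    ).to_numpy(dtype=float)
    out = {
        "n_patients": int(len(records)),
        "n_followed": int(len(followed)),
        "baseline_mean": float(baseline.mean()),
        "baseline_sd": float(baseline.std(ddof=1)),
        "effect_mean": float(change.mean()) if change.size else float("nan"),
        "change_sd": float(change.std(ddof=1)) if change.size > 1 else 0.0,
    }
    for col in records.columns:
        if col.startswith("cost_"):
            out[f"{col}_mean"] = float(records[col].mean())
    return out
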