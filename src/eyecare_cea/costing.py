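"""Micro-costing: capital annualisation, overhead allocation, currency
conversion, per-patient cost assembly, and facility pooling.

Costs are expressed in 2010 US$ per patient. Capital items (buildings,
vehicles, equipment) are amortised to an equivalent annual cost at a
discount rate; facility overheads are allocated per patient by annual
patient volume; Kwacha amounts convert at the study exchange rate of
4,729 Kwacha per US$. Facility cost profiles are pooled into the single
mean/SE pair each decision model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KWACHA_PER_USD",
    "CATEGORIES",
    "CapitalItem",
    "CostComponent",
    "FacilityCostProfile",
    "PooledCost",
    "annualize_capital",
    "overhead_per_patient",
    "convert_currency",
    "assemble_cost_profile",
    "pool_costs",
    "profiles_to_table",
]

KWACHA_PER_USD = 4729.0

CATEGORIES = (
    "general_overhead",
    "surgery_overhead",
    "equipment",
    "drugs_supplies",
    "staff",
    "spectacles",
    "transport",
)


@dataclass(frozen=True)
class CapitalItem:
    """A capital purchase to be amortised: present value (US$), useful
    life (years), and annual discount rate."""

    present_value: float
    useful_life: float
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.present_value < 0:
            raise ValueError(f"present value must be >= 0, got {self.present_value}")
        if self.useful_life < 1:
            raise ValueError(f"useful life must be >= 1 year, got {self.useful_life}")
        if self.discount_rate < 0:
            raise ValueError(f"discount rate must be >= 0, got {self.discount_rate}")


def annualize_capital(item: CapitalItem) -> float:
    """Equivalent annual cost of a capital item.

    ``PV * r / (1 - (1+r)^-L)``, i.e. present value divided by the
    annuity factor; at r = 0 this reduces to straight-line PV / L.
    """
    r, L = item.discount_rate, item.useful_life
    if r == 0:
        return item.present_value / L
    annuity_factor = (1.0 - (1.0 + r) ** (-L)) / r
    return item.present_value / annuity_factor


def overhead_per_patient(total_overhead: float, patient_volume: float) -> float:
    """Allocate an annual overhead equally across the year's patients."""
    if patient_volume <= 0:
        raise ValueError(f"patient volume must be > 0, got {patient_volume}")
    if total_overhead < 0:
        raise ValueError(f"overhead must be >= 0, got {total_overhead}")
    return total_overhead / patient_volume


def convert_currency(amount_kwacha: float) -> float:
    """Convert 2010 Kwacha to 2010 US$ at 4,729 Kwacha per US$."""
    if amount_kwacha < 0:
        raise ValueError(f"amount must be >= 0, got {amount_kwacha}")
    return amount_kwacha / KWACHA_PER_USD


@dataclass(frozen=True)
class CostComponent:
    """One per-patient cost component (2010 US$) in a closed category set."""

    category: str
    amount: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown cost category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.amount < 0:
            raise ValueError(f"cost amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class FacilityCostProfile:
    """Per-patient treatment cost at one facility.

    ``subtotal`` sums all non-transport components (the facility cost of
    delivering the intervention); ``total`` adds patient transport.
    Values are kept unrounded internally; rounding is a rendering choice.
    """

    facility: str
    intervention: str
    components: tuple[CostComponent, ...]

    @property
    def subtotal(self) -> float:
        return sum(c.amount for c in self.components if c.category != "transport")

    @property
    def total(self) -> float:
        return sum(c.amount for c in self.components)

    def amount(self, category: str) -> float:
        for c in self.components:
            if c.category == category:
                return c.amount
        return 0.0


def assemble_cost_profile(
    components,
    facility: str = "",
    intervention: str = "",
) -> FacilityCostProfile:
    """Assemble components (at most one per category) into a profile.

    ``components`` may be CostComponent objects, ``(category, amount)``
    pairs, or a ``{category: amount}`` mapping. Order is irrelevant.
    """
    if isinstance(components, dict):
        components = list(components.items())
    comps: list[CostComponent] = []
    seen: set[str] = set()
    for item in components:
        c = item if isinstance(item, CostComponent) else CostComponent(*item)
        if c.category in seen:
            raise ValueError(f"duplicate cost category {c.category!r}")
        seen.add(c.category)
        comps.append(c)
    comps.sort(key=lambda c: CATEGORIES.index(c.category))
    return FacilityCostProfile(facility, intervention, tuple(comps))


@dataclass(frozen=True)
class PooledCost:
    """Pooled mean treatment cost and its standard error (2010 US$)."""

    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"pooled mean must be > 0, got {self.mean}")
        if self.se < 0:
            raise ValueError(f"pooled se must be >= 0, got {self.se}")


def pool_costs(
    totals,
    weights,
    se_override: float | None = None,
    se_method: str = "range4",
) -> PooledCost:
    """Pool facility cost totals into a single mean/SE.

    The mean is the recruitment-weighted average of facility totals. The
    SE defaults to the between-facility range divided by 4 (a normal-range
    heuristic); a direct ``se_override`` always takes precedence so that
    externally reported SEs drive downstream uncertainty analysis.
    """
    t = np.asarray(list(totals), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if t.shape != w.shape:
        raise ValueError("totals and weights must align")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    mean = float(np.average(t, weights=w))
    if se_override is not None:
        se = float(se_override)
    elif se_method == "range4":
        se = float((t.max() - t.min()) / 4.0)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return PooledCost(mean=mean, se=se)


def profiles_to_table(profiles, round_dollars: bool = True) -> pd.DataFrame:
    """Render facility cost profiles as a component x facility table.

    One row per cost category plus subtotal/total rows; one column per
    (facility, intervention). Rounding to the nearest dollar is applied
    for display only.
    """
    cols: dict[tuple[str, str], dict[str, float]] = {}
    for p in profiles:
        col = {cat: p.amount(cat) for cat in CATEGORIES}
        col["subtotal"] = p.subtotal
        col["total"] = p.total
        cols[(p.facility, p.intervention)] = col
    df = pd.DataFrame(cols)
    df = df.reindex(list(CATEGORIES) + ["subtotal", "total"])
    if round_dollars:
        df = df.round(0)
    return df
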