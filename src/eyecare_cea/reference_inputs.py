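"""Canonical published inputs of the Zambian eye-care cost-effectiveness
study this package implements.

These are the study's printed per-patient cost components by facility,
the pooled model parameters (means and standard errors), the cohort
utility summaries, and the derived calibration constants. They serve as
the default configuration so that a bare run reproduces the published
deterministic and probabilistic results, and as fixtures for tests.

All monetary values are 2010 US$ per patient.
"""

from __future__ import annotations

from .costing import FacilityCostProfile, assemble_cost_profile

__all__ = [
    "FACILITY_COST_COMPONENTS",
    "facility_cost_profiles",
    "POOLED_COSTS",
    "UTILITY_PARAMS",
    "TRANSITION_PARAMS",
    "COHORT_UTILITY_SUMMARY",
    "DISCOUNT_RATE",
    "START_AGE",
    "GNI_THRESHOLD_USD",
    "PATIENT_VOLUMES",
    "NO_INTERVENTION_QALYS_CATARACT",
    "IMPLIED_ANNUITY_AGE63",
]

#: Per-patient cost components (2010 US$) by facility and intervention.
#: Livingstone's cataract surgery overhead was not collected (absent key).
FACILITY_COST_COMPONENTS: dict[tuple[str, str], dict[str, float]] = {
    ("LEH", "cataract"): {
        "general_overhead": 31,
        "surgery_overhead": 21,
        "equipment": 8,
        "drugs_supplies": 33,
        "staff": 18,
        "transport": 17,
    },
    ("LEH", "refraction"): {
        "general_overhead": 31,
        "equipment": 1,
        "drugs_supplies": 10,
        "staff": 12,
        "spectacles": 15,
        "transport": 18,
    },
    ("Choma", "cataract"): {
        "general_overhead": 4,
        "surgery_overhead": 9,
        "equipment": 2,
        "drugs_supplies": 18,
        "staff": 16,
        "transport": 4,
    },
    ("Choma", "refraction"): {
        "general_overhead": 4,
        "equipment": 5,
        "drugs_supplies": 0.5,
        "staff": 7,
        "spectacles": 4,
        "transport": 1,
    },
    ("Livingstone", "cataract"): {
        "general_overhead": 30,
        "equipment": 2,
        "drugs_supplies": 18,
        "staff": 26,
        "transport": 4,
    },
    ("Livingstone", "refraction"): {
        "general_overhead": 30,
        "equipment": 12,
        "drugs_supplies": 0.8,
        "staff": 3,
        "spectacles": 20,
        "transport": 2,
    },
}


def facility_cost_profiles() -> list[FacilityCostProfile]:
    """The six published facility cost profiles as domain objects."""
    return [
        assemble_cost_profile(components, facility=fac, intervention=tx)
        for (fac, tx), components in FACILITY_COST_COMPONENTS.items()
    ]


#: Recruitment-weighted pooled treatment costs, mean (se), 2010 US$.
POOLED_COSTS = {"cataract": (92.0, 3.4), "refraction": (72.0, 7.8)}

#: Cohort-study utility means (se) feeding the models.
UTILITY_PARAMS = {
    "cataract": {"u_base": (0.782, 0.017), "u_post": (0.832, 0.015)},
    "refraction": {"u_base": (0.850, 0.022), "u_post": (0.925, 0.018)},
}

#: Annual transition probabilities, mean (se).
TRANSITION_PARAMS = {
    "cataract": {"p_deteriorate": (0.04, 0.01)},
    "refraction": {"loss_p1": (0.05, 0.01), "loss_pH": (0.90, None)},
}

#: Patient-level EQ-5D utility summaries (mean, sd, min, max, n).
COHORT_UTILITY_SUMMARY = {
    ("cataract", "baseline"): {"mean": 0.782, "sd": 0.150, "min": 0.130, "max": 1.0, "n": 77},
    ("cataract", "followup"): {"mean": 0.832, "sd": 0.129, "min": 0.417, "max": 1.0, "n": 77},
    ("refraction", "baseline"): {"mean": 0.850, "sd": 0.139, "min": 0.361, "max": 1.0, "n": 41},
    ("refraction", "followup"): {"mean": 0.925, "sd": 0.117, "min": 0.509, "max": 1.0, "n": 41},
}

DISCOUNT_RATE = 0.03
START_AGE = {"cataract": 63, "refraction": 39}
GNI_THRESHOLD_USD = 1160.0

#: Annual eye-patient volumes by facility (2010), for overhead allocation.
PATIENT_VOLUMES = {"LEH": 17_413, "Livingstone": 3_039, "Choma": 2_682}

#: Published lifetime discounted QALYs of the no-surgery cataract arm.
NO_INTERVENTION_QALYS_CATARACT = 7.519

#: Discounted survival-weighted life-year annuity from age 63 implied by
#: the no-surgery QALY total and the baseline utility: 7.519 / 0.782.
IMPLIED_ANNUITY_AGE63 = NO_INTERVENTION_QALYS_CATARACT / 0.782
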