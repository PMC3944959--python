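"""Run configuration: YAML loading, canonical defaults, model assembly.

A run is described by a single mapping (YAML file or dict). Every key has
a default drawn from the published study inputs, so an empty config
reproduces the canonical analysis. Keys:

``life_table``
    ``path`` — CSV life table (``age,qx`` or ``age_start,age_end,nqx``);
    ``flat_calibrated`` — calibrate a constant annual death probability
    so the discounted annuity from age 63 matches the published implied
    value (default when no path is given);
    ``synthetic: {level, shape, max_age}`` — Gompertz stand-in table.
``cataract`` / ``refraction``
    model parameter blocks (cost, u_base, u_post, p_deteriorate /
    loss_p1, loss_pH, horizon, start_age).
``discount_rate`` — shared annual discount rate (default 0.03).
``conventions`` — ``half_cycle_correction`` (default false),
    ``cumulative_loss_schedule`` (default false).
``psa`` — ``n_iter`` (default 10000), ``seed`` (default 1),
    ``thresholds: {max, step}``.
``costing`` — ``discount_rate`` (default 0.03), ``se_method``
    (``override``/``range4``), ``include_transport`` (default true).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from . import reference_inputs as ref
from .life_tables import (
    LifeTable,
    calibrate_flat_mortality,
    flat_life_table,
    load_life_table,
    synthetic_life_table,
)
from .markov import CataractParams, RefractionParams

__all__ = ["default_config", "load_config", "build_life_table",
           "build_cataract_params", "build_refraction_params", "config_hash"]


def default_config() -> dict:
    """The canonical configuration: published study inputs throughout."""
    return {
        "life_table": {"flat_calibrated": True},
        "discount_rate": ref.DISCOUNT_RATE,
        "conventions": {
            "half_cycle_correction": False,
            "cumulative_loss_schedule": False,
        },
        "cataract": {
            "cost": ref.POOLED_COSTS["cataract"][0],
            "cost_se": ref.POOLED_COSTS["cataract"][1],
            "u_base": ref.UTILITY_PARAMS["cataract"]["u_base"][0],
            "u_base_se": ref.UTILITY_PARAMS["cataract"]["u_base"][1],
            "u_post": ref.UTILITY_PARAMS["cataract"]["u_post"][0],
            "u_post_se": ref.UTILITY_PARAMS["cataract"]["u_post"][1],
            "p_deteriorate": ref.TRANSITION_PARAMS["cataract"]["p_deteriorate"][0],
            "p_deteriorate_se": ref.TRANSITION_PARAMS["cataract"]["p_deteriorate"][1],
            "start_age": ref.START_AGE["cataract"],
        },
        "refraction": {
            "cost": ref.POOLED_COSTS["refraction"][0],
            "cost_se": ref.POOLED_COSTS["refraction"][1],
            "u_base": ref.UTILITY_PARAMS["refraction"]["u_base"][0],
            "u_base_se": ref.UTILITY_PARAMS["refraction"]["u_base"][1],
            "u_post": ref.UTILITY_PARAMS["refraction"]["u_post"][0],
            "u_post_se": ref.UTILITY_PARAMS["refraction"]["u_post"][1],
            "loss_p1": ref.TRANSITION_PARAMS["refraction"]["loss_p1"][0],
            "loss_p1_se": ref.TRANSITION_PARAMS["refraction"]["loss_p1"][1],
            "loss_pH": ref.TRANSITION_PARAMS["refraction"]["loss_pH"][0],
            "horizon": 5,
            "start_age": ref.START_AGE["refraction"],
        },
        "psa": {
            "n_iter": 10_000,
            "seed": 1,
            "thresholds": {"max": 2000, "step": 10},
        },
        "costing": {
            "discount_rate": 0.03,
            "se_method": "override",
            "include_transport": True,
        },
    }


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the canonical defaults with a YAML file and/or overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, copy.deepcopy(overrides))
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of a resolved configuration, for provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_life_table(cfg: dict) -> LifeTable:
    """Construct the life table a config asks for.

    Precedence: explicit ``path`` > ``synthetic`` block > flat table
    calibrated to the published implied annuity from age 63.
    """
    lt_cfg = cfg.get("life_table", {})
    if lt_cfg.get("path"):
        path = Path(lt_cfg["path"])
        if not path.exists():
            raise FileNotFoundError(f"life_table.path does not exist: {path}")
        return load_life_table(path)
    if lt_cfg.get("synthetic"):
        syn = lt_cfg["synthetic"]
        return synthetic_life_table(
            level=syn["level"],
            shape=syn["shape"],
            max_age=syn.get("max_age", 100),
        )
    rate = cfg.get("discount_rate", ref.DISCOUNT_RATE)
    q = calibrate_flat_mortality(
        ref.IMPLIED_ANNUITY_AGE63, start_age=ref.START_AGE["cataract"], rate=rate
    )
    return flat_life_table(q)


def build_cataract_params(cfg: dict, life_table: LifeTable | None = None) -> CataractParams:
    lt = life_table if life_table is not None else build_life_table(cfg)
    c = cfg["cataract"]
    return CataractParams(
        life_table=lt,
        surgery_cost=c["cost"],
        u_base=c["u_base"],
        u_post=c["u_post"],
        p_deteriorate=c["p_deteriorate"],
        discount_rate=cfg["discount_rate"],
        start_age=c["start_age"],
        half_cycle_correction=cfg["conventions"]["half_cycle_correction"],
    )


def build_refraction_params(cfg: dict, life_table: LifeTable | None = None) -> RefractionParams:
    lt = life_table if life_table is not None else build_life_table(cfg)
    r = cfg["refraction"]
    return RefractionParams(
        life_table=lt,
        spectacles_cost=r["cost"],
        u_base=r["u_base"],
        u_post=r["u_post"],
        loss_p1=r["loss_p1"],
        loss_pH=r["loss_pH"],
        horizon=r["horizon"],
        discount_rate=cfg["discount_rate"],
        start_age=r["start_age"],
        cumulative_schedule=cfg["conventions"]["cumulative_loss_schedule"],
        half_cycle_correction=cfg["conventions"]["half_cycle_correction"],
    )
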