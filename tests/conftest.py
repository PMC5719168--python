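"""Shared helpers: reduced demographies and deterministic toy datasets."""

from __future__ import annotations

import numpy as np
import pytest

from steppeabc import build_model, default_config
from steppeabc.config import CENTRAL_EUROPE, EASTERN_EUROPE
from steppeabc.demography import DemographicModel, ParameterDraw


def single_region_config(n: int, age_bp: float | list = 0.0, gen_time: float = 25.0):
    """A config with one sampled population in one panmictic region."""
    cfg = default_config()
    cfg["generation_time_years"] = gen_time
    cfg["populations"] = [
        {"name": "A", "region": CENTRAL_EUROPE, "n": n, "age_bp": age_bp}
    ]
    return cfg


def single_region_model(n: int, age_bp: float | list = 0.0) -> DemographicModel:
    return build_model("NOMIG", single_region_config(n, age_bp))


def constant_size_draw(
    model: DemographicModel, N: float, mu: float = 0.0
) -> ParameterDraw:
    """All regions at size N, splits pushed far beyond any coalescence."""
    values = {
        "N_CentralEurope": N,
        "N_EasternEurope": N,
        "N_NearEast": N,
        "N_ancestral": N,
        "t_split_CE_NE": 1e12,
        "t_split_EE": 2e12,
        "mu": mu,
    }
    for e in model.events:
        values[e.time_param] = 0.5 * sum(
            b for b in e.time_constraint if np.isfinite(b)
        )
        values[e.proportion_param] = 0.0
    return ParameterDraw(values=values, model_name=model.name)


def default_draw_values(model_name: str = "MIG2") -> dict[str, float]:
    """A hand-valid parameter vector for the default six-population design."""
    values = {
        "N_CentralEurope": 5000.0,
        "N_EasternEurope": 8000.0,
        "N_NearEast": 6000.0,
        "N_ancestral": 10000.0,
        "t_split_CE_NE": 600.0,
        "t_split_EE": 1200.0,
        "mu": 4e-8,
        "t1": 220.0,
        "m1": 0.3,
        "t2": 188.0,
        "m2": 0.5,
        "t3": 165.0,
        "m3": 0.3,
    }
    model = build_model(model_name, default_config())
    keep = set(model.parameter_names)
    return {k: v for k, v in values.items() if k in keep}


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()
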