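"""Demographic models of late-Neolithic migration between three regions.

Five competing models describe the same three regional mtDNA lineages
(Central Europe, Eastern Europe, Near East) with six dated sampled cultures,
and differ only in their pulse-migration events:

========  =========================================================
NOMIG     no migration
MIG1      event 1: Eastern -> Central Europe, before the GAC samples
MIG2      event 2: Eastern -> Central Europe, after the GAC samples
          but before the Corded Ware samples
MIG12     events 1 and 2
MIG23     event 2 plus event 3: a back-migration Central -> Eastern
          Europe after the Corded Ware samples
========  =========================================================

Within a region all sampled cultures lie on one continuous lineage; a pulse
of proportion ``m`` at time ``t`` means that, tracing ancestry backward, each
lineage present in the destination region at ``t`` derives from the source
region with probability ``m``.

The regional topology (a package design choice; the inter-region tree is a
configurable input) is: Central Europe and the Near East merge, backward in
time, at ``t_split_CE_NE``; that joint lineage merges with Eastern Europe at
the older ``t_split_EE`` into a single ancestral population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .config import (
    CENTRAL_EUROPE,
    EASTERN_EUROPE,
    MODEL_NAMES,
    NEAR_EAST,
    REGIONS,
    default_config,
)

#: event id -> (source region, destination region), forward in time
EVENT_DIRECTIONS = {
    1: (EASTERN_EUROPE, CENTRAL_EUROPE),
    2: (EASTERN_EUROPE, CENTRAL_EUROPE),
    3: (CENTRAL_EUROPE, EASTERN_EUROPE),
}

#: model name -> set of migration events it includes
MODEL_EVENTS: dict[str, tuple[int, ...]] = {
    "NOMIG": (),
    "MIG1": (1,),
    "MIG2": (2,),
    "MIG12": (1, 2),
    "MIG23": (2, 3),
}

BASE_PARAMETERS = (
    "N_CentralEurope",
    "N_EasternEurope",
    "N_NearEast",
    "N_ancestral",
    "t_split_CE_NE",
    "t_split_EE",
    "mu",
)

MAX_RESAMPLE_ATTEMPTS = 100_000


class DemographyError(ValueError):
    """Invalid model configuration or parameter draw."""


@dataclass(frozen=True)
class SampledPopulation:
    """A dated sampled culture assigned to a regional lineage.

    ``age_bp`` may be a single age (years before present) applied to all
    samples, or a sequence of per-sample ages of length ``n_samples``.
    """

    name: str
    region: str
    n_samples: int
    age_bp: float | tuple[float, ...]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise DemographyError(
                f"population {self.name!r}: unknown region {self.region!r}"
            )
        if self.n_samples < 1:
            raise DemographyError(f"population {self.name!r}: n_samples must be >= 1")
        ages = self.ages_bp()
        if len(ages) != self.n_samples:
            raise DemographyError(
                f"population {self.name!r}: {len(ages)} ages for "
                f"{self.n_samples} samples"
            )
        if any(a < 0 for a in ages):
            raise DemographyError(f"population {self.name!r}: negative age")

    def ages_bp(self) -> tuple[float, ...]:
        if isinstance(self.age_bp, (int, float)):
            return (float(self.age_bp),) * self.n_samples
        return tuple(float(a) for a in self.age_bp)

    def ages_gen(self, generation_time_years: float) -> tuple[float, ...]:
        return tuple(a / generation_time_years for a in self.ages_bp())

    def age_gen(self, generation_time_years: float) -> float:
        """Oldest sample age in generations (the population's tip age)."""
        return max(self.ages_gen(generation_time_years))


@dataclass(frozen=True)
class MigrationEvent:
    """An instantaneous pulse of ancestry between two regional lineages."""

    event_id: int
    source_region: str
    dest_region: str
    time_param: str
    proportion_param: str
    time_constraint: tuple[float, float]  # (lower, upper) in generations

    def __post_init__(self) -> None:
        if self.source_region == self.dest_region:
            raise DemographyError("migration source and destination must differ")


@dataclass(frozen=True)
class DemographicModel:
    """One of the five competing regional demographies."""

    name: str
    populations: tuple[SampledPopulation, ...]
    events: tuple[MigrationEvent, ...]
    generation_time_years: float

    @property
    def event_ids(self) -> tuple[int, ...]:
        return tuple(e.event_id for e in self.events)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = list(BASE_PARAMETERS)
        for e in self.events:
            names.append(e.time_param)
            names.append(e.proportion_param)
        return tuple(names)

    def population(self, name: str) -> SampledPopulation:
        for p in self.populations:
            if p.name == name:
                return p
        raise DemographyError(f"no population named {name!r}")

    def tip_age_gen(self, name: str) -> float:
        return self.population(name).age_gen(self.generation_time_years)

    @property
    def n_samples(self) -> int:
        return sum(p.n_samples for p in self.populations)


@dataclass(frozen=True)
class Prior:
    """A one-dimensional marginal prior (uniform or log-uniform)."""

    name: str
    family: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "loguniform"):
            raise DemographyError(f"unknown prior family {self.family!r}")
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise DemographyError(f"prior {self.name!r}: non-finite bounds")
        if self.low > self.high:
            raise DemographyError(f"prior {self.name!r}: low > high")
        if self.family == "loguniform" and self.low <= 0:
            raise DemographyError(f"prior {self.name!r}: log-uniform needs low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.low == self.high:  # point mass
            return self.low
        if self.family == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass(frozen=True)
class PriorSpec:
    """Named marginal priors covering every model parameter."""

    priors: Mapping[str, Prior]

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "PriorSpec":
        priors = {
            name: Prior(name, spec["family"], float(spec["low"]), float(spec["high"]))
            for name, spec in cfg.items()
        }
        return cls(priors=priors)

    def __getitem__(self, name: str) -> Prior:
        try:
            return self.priors[name]
        except KeyError:
            raise DemographyError(f"no prior declared for parameter {name!r}") from None

    def covers(self, names: Iterable[str]) -> bool:
        return all(n in self.priors for n in names)


@dataclass(frozen=True)
class ParameterDraw:
    """A concrete parameter vector for one model."""

    values: Mapping[str, float]
    model_name: str
    seed: int | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def _event_window(
    event_id: int, populations: Sequence[SampledPopulation], gen_time: float
) -> tuple[float, float]:
    """Chronological window (generations) for a migration event.

    Event 1 predates the GAC samples; event 2 falls between the Corded Ware
    and GAC sample ages; event 3 falls between the Srubnaya and Corded Ware
    sample ages.  Upper bounds involving split times are enforced separately
    because split times are themselves drawn from priors.
    """
    ages = {p.name: p.age_gen(gen_time) for p in populations}
    if event_id == 1:
        return (ages["GAC"], math.inf)
    if event_id == 2:
        return (ages["CordedWare"], ages["GAC"])
    if event_id == 3:
        return (ages["Srubnaya"], ages["CordedWare"])
    raise DemographyError(f"unknown event id {event_id}")


def build_model(name: str, config: Mapping[str, Any] | None = None) -> DemographicModel:
    """Construct one of the five models from a run configuration."""
    if name not in MODEL_NAMES:
        raise DemographyError(
            f"unknown model {name!r}; expected one of {MODEL_NAMES}"
        )
    cfg = config if config is not None else default_config()
    gen_time = float(cfg["generation_time_years"])
    pops = tuple(
        SampledPopulation(
            name=p["name"],
            region=p["region"],
            n_samples=int(p["n"]),
            age_bp=tuple(p["age_bp"]) if isinstance(p["age_bp"], (list, tuple)) else float(p["age_bp"]),
        )
        for p in cfg["populations"]
    )
    declared_regions = set(REGIONS)
    for p in pops:
        if p.region not in declared_regions:
            raise DemographyError(f"population {p.name!r} in undeclared region")
    events = []
    for eid in MODEL_EVENTS[name]:
        src, dst = EVENT_DIRECTIONS[eid]
        events.append(
            MigrationEvent(
                event_id=eid,
                source_region=src,
                dest_region=dst,
                time_param=f"t{eid}",
                proportion_param=f"m{eid}",
                time_constraint=_event_window(eid, pops, gen_time),
            )
        )
    return DemographicModel(
        name=name,
        populations=pops,
        events=tuple(events),
        generation_time_years=gen_time,
    )


def constraint_violations(draw: ParameterDraw, model: DemographicModel) -> list[str]:
    """All event-ordering / topology constraints violated by ``draw``."""
    v = draw.values
    out: list[str] = []
    t_cn = v["t_split_CE_NE"]
    t_ee = v["t_split_EE"]
    if not t_cn < t_ee:
        out.append("t_split_CE_NE must be younger than t_split_EE")
    oldest = {reg: 0.0 for reg in REGIONS}
    for p in model.populations:
        oldest[p.region] = max(oldest[p.region], p.age_gen(model.generation_time_years))
    if not t_cn > max(oldest[CENTRAL_EUROPE], oldest[NEAR_EAST]):
        out.append("t_split_CE_NE must predate all Central Europe / Near East tips")
    if not t_ee > oldest[EASTERN_EUROPE]:
        out.append("t_split_EE must predate all Eastern Europe tips")
    for e in model.events:
        t = v[e.time_param]
        m = v[e.proportion_param]
        lo, hi = e.time_constraint
        if not (0.0 <= m <= 1.0):
            out.append(f"{e.proportion_param} outside [0, 1]")
        if not lo < t:
            out.append(f"{e.time_param} must be older than {lo:.6g} gen")
        if not (math.isinf(hi) or t < hi):
            out.append(f"{e.time_param} must be younger than {hi:.6g} gen")
        # every event happens while both regions still exist
        if not (t < t_cn and t < t_ee):
            out.append(f"{e.time_param} must be younger than the regional splits")
    return out


def draw_is_valid(draw: ParameterDraw, model: DemographicModel) -> bool:
    return not constraint_violations(draw, model)


def sample_parameters(
    model: DemographicModel,
    priors: PriorSpec,
    seed: int | np.random.Generator,
) -> ParameterDraw:
    """Draw a valid parameter vector from the priors.

    Draws are rejection-resampled until every event-ordering constraint holds
    (truncated-prior semantics), up to ``MAX_RESAMPLE_ATTEMPTS``.
    """
    names = model.parameter_names
    missing = [n for n in names if n not in priors.priors]
    if missing:
        raise DemographyError(f"missing priors for parameters: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        values = {n: priors[n].sample(rng) for n in names}
        draw = ParameterDraw(values=values, model_name=model.name, seed=seed_val)
        if draw_is_valid(draw, model):
            return draw
    raise DemographyError(
        f"no valid draw for model {model.name} in {MAX_RESAMPLE_ATTEMPTS} attempts; "
        "the priors may make the event-time constraints unsatisfiable"
    )


def enforce_event_order(
    draw: ParameterDraw,
    model: DemographicModel,
    priors: PriorSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> ParameterDraw:
    """Return a draw satisfying every event-ordering constraint.

    A valid draw is returned unchanged.  An invalid draw is resampled from
    ``priors`` (rejection semantics) when they are supplied; otherwise a
    ``DemographyError`` listing the violations is raised.
    """
    if draw_is_valid(draw, model):
        return draw
    if priors is None:
        raise DemographyError(
            "invalid draw: " + "; ".join(constraint_violations(draw, model))
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sample_parameters(model, priors, rng)


def point_mass_priors(values: Mapping[str, float]) -> PriorSpec:
    """Degenerate priors fixing every parameter (useful for PODs and tests)."""
    return PriorSpec(
        priors={n: Prior(n, "uniform", float(v), float(v)) for n, v in values.items()}
    )
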