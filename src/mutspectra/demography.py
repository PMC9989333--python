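"""Demographic models: populations, epochs, splits, migration.

A :class:`PopulationModel` describes, backward in time, a set of populations
whose diploid sizes change piecewise (instantaneous changes at epoch
boundaries, exponential trajectories within an epoch), joined into a single
tree of ancestors by split events, with optional lineage migration.  Sizes
are diploid individuals (N); the coalescent rate for a lineage pair is
1/(2N) per generation.  Times are generations before the present.

Three "basic" single-split models (constant / decline / growth) are built in
code; the human out-of-Africa and four-population chimpanzee models ship as
YAML config files under ``mutspectra/data/models`` (parameter values are
data, not code, and each file states where its numbers come from).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Epoch",
    "SplitEvent",
    "MigrationRate",
    "Population",
    "PopulationModel",
    "ModelSchemaError",
    "ModelValidationError",
    "BASIC_VARIANTS",
    "build_basic_model",
    "load_model",
    "shipped_model_path",
    "validate",
    "years_to_generations",
    "generations_to_years",
]

#: Ancestral size shared by the three basic models (diploid individuals).
BASIC_ANCESTRAL_SIZE = 10_000

#: Post-split size of the derived population in each basic model variant.
BASIC_VARIANTS = {"constant": 10_000, "decline": 1_000, "growth": 100_000}

#: Default time of the basic-model split, generations before present.  Long
#: enough for private variation to accumulate, short relative to N.
DEFAULT_BASIC_SPLIT_TIME = 4_000.0


class ModelSchemaError(ValueError):
    """A model config document does not follow the expected schema."""


class ModelValidationError(ValueError):
    """A structurally parseable model violates its invariants."""


@dataclass(frozen=True)
class Epoch:
    """One piece of a population's size history, looking backward in time.

    ``population_size`` is the diploid size at ``start_time`` (the epoch
    boundary closest to the present).  ``growth_rate`` is the forward-time
    per-generation exponential rate, so going backward within the epoch

        N(t) = population_size * exp(-growth_rate * (t - start_time)).
    """

    start_time: float
    population_size: float
    growth_rate: float = 0.0

    def size_at(self, t: float) -> float:
        if self.growth_rate == 0.0:
            return self.population_size
        return self.population_size * math.exp(-self.growth_rate * (t - self.start_time))


@dataclass(frozen=True)
class SplitEvent:
    """Backward in time, all lineages of ``child_population`` move into
    ``parent_population`` at ``time`` generations before present."""

    time: float
    child_population: str
    parent_population: str


@dataclass(frozen=True)
class MigrationRate:
    """Backward-in-time lineage relocation: a lineage currently in ``source``
    jumps to ``dest`` with probability ``rate`` per generation, while the
    current time lies in ``active_interval`` (generations, [start, end))."""

    source: str
    dest: str
    rate: float
    active_interval: tuple[float, float] = (0.0, math.inf)

    def active_at(self, t: float) -> bool:
        lo, hi = self.active_interval
        return lo <= t < hi


@dataclass(frozen=True)
class Population:
    id: str
    epochs: tuple[Epoch, ...]

    def epoch_at(self, t: float) -> Epoch:
        chosen = self.epochs[0]
        for e in self.epochs:
            if e.start_time <= t:
                chosen = e
            else:
                break
        return chosen

    def size_at(self, t: float) -> float:
        return self.epoch_at(t).size_at(t)


@dataclass(frozen=True)
class PopulationModel:
    populations: tuple[Population, ...]
    splits: tuple[SplitEvent, ...] = ()
    migrations: tuple[MigrationRate, ...] = ()
    species_tag: str = "generic"
    generation_time_years: float = 25.0

    def population(self, pid: str) -> Population:
        for p in self.populations:
            if p.id == pid:
                return p
        raise KeyError(f"no population {pid!r} in model")

    @property
    def population_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.populations)

    def split_of(self, child: str) -> Optional[SplitEvent]:
        for s in self.splits:
            if s.child_population == child:
                return s
        return None

    @property
    def root(self) -> str:
        children = {s.child_population for s in self.splits}
        roots = [p.id for p in self.populations if p.id not in children]
        if len(roots) != 1:
            raise ModelValidationError(f"model has {len(roots)} root populations")
        return roots[0]


# ---------------------------------------------------------------------------
# builders / loaders


def build_basic_model(
    variant: str,
    split_time: float = DEFAULT_BASIC_SPLIT_TIME,
) -> PopulationModel:
    """One of the three single-split models used to isolate demography.

    An ancestral population of 10,000 diploids; at ``split_time`` generations
    before present a derived population branches off at 10,000 (constant),
    1,000 (decline) or 100,000 (growth) diploids and keeps that size to the
    present.  No migration.  (A forward simulator would need a 10*Ne burn-in
    to reach mutation-drift equilibrium; the coalescent engine samples the
    equilibrium directly, so no burn-in parameter appears here.)
    """
    if variant not in BASIC_VARIANTS:
        raise ValueError(
            f"unknown basic model variant {variant!r}; expected one of {sorted(BASIC_VARIANTS)}"
        )
    if split_time <= 0:
        raise ValueError("split_time must be positive")
    derived_size = BASIC_VARIANTS[variant]
    ancestral = Population("ancestral", (Epoch(0.0, BASIC_ANCESTRAL_SIZE),))
    derived = Population("derived", (Epoch(0.0, derived_size),))
    return PopulationModel(
        populations=(ancestral, derived),
        splits=(SplitEvent(split_time, "derived", "ancestral"),),
        species_tag="generic",
        generation_time_years=25.0,
    )


def _as_float(value, what: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ModelSchemaError(f"{what} must be a number, got {value!r}") from None


def load_model(source: Union[str, Path, Mapping]) -> PopulationModel:
    """Load and validate a model from a YAML document or mapping.

    Schema (times in generations unless ``time_units: years``)::

        species: chimpanzee
        generation_time_years: 20
        time_units: generations
        populations:
          - id: Central
            epochs: [{start: 0, size: 72000, growth_rate: 0}, ...]
        splits:
          - {time: 7500, child: Eastern, parent: Central}
        migrations:
          - {source: Central, dest: Eastern, rate: 5.0e-5, start: 0, end: 7500}
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or not doc:
        raise ModelSchemaError("model document must be a non-empty mapping")
    if "populations" not in doc:
        raise ModelSchemaError("model document lacks a 'populations' section")

    gen_time = _as_float(doc.get("generation_time_years", 25.0), "generation_time_years")
    if gen_time <= 0:
        raise ModelSchemaError("generation_time_years must be positive")
    units = doc.get("time_units", "generations")
    if units not in ("generations", "years"):
        raise ModelSchemaError(f"time_units must be 'generations' or 'years', got {units!r}")
    scale = 1.0 / gen_time if units == "years" else 1.0

    populations = []
    for pdoc in doc["populations"]:
        if not isinstance(pdoc, Mapping) or "id" not in pdoc or "epochs" not in pdoc:
            raise ModelSchemaError("each population needs 'id' and 'epochs'")
        epochs = []
        for edoc in pdoc["epochs"]:
            if not isinstance(edoc, Mapping) or "size" not in edoc:
                raise ModelSchemaError("each epoch needs at least a 'size'")
            epochs.append(
                Epoch(
                    start_time=_as_float(edoc.get("start", 0.0), "epoch start") * scale,
                    population_size=_as_float(edoc["size"], "epoch size"),
                    growth_rate=_as_float(edoc.get("growth_rate", 0.0), "growth_rate") / scale
                    if units == "years"
                    else _as_float(edoc.get("growth_rate", 0.0), "growth_rate"),
                )
            )
        epochs.sort(key=lambda e: e.start_time)
        populations.append(Population(str(pdoc["id"]), tuple(epochs)))

    splits = []
    for sdoc in doc.get("splits", []) or []:
        for key in ("time", "child", "parent"):
            if key not in sdoc:
                raise ModelSchemaError(f"split event lacks {key!r}")
        splits.append(
            SplitEvent(_as_float(sdoc["time"], "split time") * scale, str(sdoc["child"]), str(sdoc["parent"]))
        )

    migrations = []
    for mdoc in doc.get("migrations", []) or []:
        for key in ("source", "dest", "rate"):
            if key not in mdoc:
                raise ModelSchemaError(f"migration entry lacks {key!r}")
        start = _as_float(mdoc.get("start", 0.0), "migration start") * scale
        end = mdoc.get("end", None)
        end = math.inf if end is None else _as_float(end, "migration end") * scale
        migrations.append(
            MigrationRate(str(mdoc["source"]), str(mdoc["dest"]), _as_float(mdoc["rate"], "migration rate"), (start, end))
        )

    model = PopulationModel(
        populations=tuple(populations),
        splits=tuple(splits),
        migrations=tuple(migrations),
        species_tag=str(doc.get("species", "generic")),
        generation_time_years=gen_time,
    )
    problems = validate(model)
    if problems:
        raise ModelValidationError("; ".join(problems))
    return model


def shipped_model_path(name: str) -> Path:
    """Path of a model config shipped with the package (``human``/``chimpanzee``)."""
    fname = {"human": "human_ooa.yaml", "chimpanzee": "chimpanzee.yaml"}.get(name, name)
    path = resources.files("mutspectra") / "data" / "models" / fname
    if not path.is_file():  # pragma: no cover - defensive
        raise FileNotFoundError(f"no shipped model {name!r}")
    return Path(str(path))


# ---------------------------------------------------------------------------
# validation


def validate(model: PopulationModel) -> list[str]:
    """Return a list of invariant violations (empty when the model is sound).

    Checks type invariants (positive sizes, ordered epochs, migration rates
    in [0, 1]) and that the split events form a tree: exactly one root, every
    other population joined to a parent that is still extant (backward in
    time) at the split time, and no cycles — so backward lineage movement is
    well defined at every epoch.
    """
    problems: list[str] = []
    ids = [p.id for p in model.populations]
    if len(set(ids)) != len(ids):
        problems.append("duplicate population ids")
    if not ids:
        problems.append("model has no populations")
        return problems
    if model.generation_time_years <= 0:
        problems.append("generation_time_years must be positive")

    for p in model.populations:
        if not p.epochs:
            problems.append(f"population {p.id}: no epochs")
            continue
        prev = -math.inf
        for e in p.epochs:
            if e.population_size <= 0:
                problems.append(f"population {p.id}: epoch size {e.population_size} <= 0")
            if e.start_time < 0:
                problems.append(f"population {p.id}: epoch start {e.start_time} < 0")
            if e.start_time <= prev:
                problems.append(f"population {p.id}: epochs not strictly time-ordered")
            prev = e.start_time
        if p.epochs[0].start_time != 0:
            problems.append(f"population {p.id}: first epoch must start at time 0")

    id_set = set(ids)
    seen_children: set[str] = set()
    for s in model.splits:
        if s.time <= 0:
            problems.append(f"split {s.child_population}->{s.parent_population}: time must be > 0")
        if s.child_population == s.parent_population:
            problems.append(f"split at t={s.time}: child equals parent")
        for pid in (s.child_population, s.parent_population):
            if pid not in id_set:
                problems.append(f"split references unknown population {pid!r}")
        if s.child_population in seen_children:
            problems.append(f"population {s.child_population} has more than one split")
        seen_children.add(s.child_population)

    roots = [pid for pid in ids if pid not in seen_children]
    if len(roots) != 1:
        problems.append(f"expected exactly one root population, found {len(roots)}")

    # tree reachability + parent extant at split time
    split_by_child = {s.child_population: s for s in model.splits if s.child_population in id_set}
    for pid in ids:
        seen_path: set[str] = set()
        cur = pid
        while cur in split_by_child:
            if cur in seen_path:
                problems.append(f"split events contain a cycle through {cur!r}")
                break
            seen_path.add(cur)
            s = split_by_child[cur]
            parent_split = split_by_child.get(s.parent_population)
            if parent_split is not None and parent_split.time < s.time:
                problems.append(
                    f"split of {s.child_population} at t={s.time} into {s.parent_population},"
                    f" which itself merged away at t={parent_split.time}"
                )
            cur = s.parent_population

    for m in model.migrations:
        if not (0.0 <= m.rate <= 1.0):
            problems.append(f"migration {m.source}->{m.dest}: rate {m.rate} outside [0, 1]")
        if m.source == m.dest:
            problems.append(f"migration {m.source}->{m.dest}: source equals dest")
        for pid in (m.source, m.dest):
            if pid not in id_set:
                problems.append(f"migration references unknown population {pid!r}")
        lo, hi = m.active_interval
        if not (0 <= lo < hi):
            problems.append(f"migration {m.source}->{m.dest}: bad active interval {m.active_interval}")
    return problems


# ---------------------------------------------------------------------------
# time-unit conversion


def years_to_generations(years: float, model: PopulationModel) -> float:
    """Convert years before present to generations using the model's
    generation time (25 y for the human model, 20 y for chimpanzee)."""
    if years < 0:
        raise ValueError("years must be non-negative")
    return years / model.generation_time_years


def generations_to_years(generations: float, model: PopulationModel) -> float:
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return generations * model.generation_time_years
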