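"""Strict run configuration (YAML).

A run config has five optional sections — ``system``, ``forcefield``,
``restraints``, ``mc``, ``analysis`` — plus ``output``. Unknown keys are
rejected with the offending key named; all defaults are the dataclass
defaults of the corresponding module. Configs round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .forcefield import ForceField
from .moves import MoveSet
from .restraints import RestraintParams

__all__ = ["RunConfig", "SystemConfig", "MCConfig", "AnalysisConfig", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


def _take(d: dict, section: str, allowed: set[str]) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {', '.join(sorted(unknown))}"
        )
    return d


def _build_dataclass(cls, d: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    _take(d, section, names)
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' section: {exc}") from exc


@dataclass(frozen=True)
class SystemConfig:
    """Which fiber to build and how to annotate it."""

    builder: str = "uniform"  # uniform | lifelike | gene | fixture
    n_cores: int = 50
    linker_bp: float = 44.0
    seed: int = 0
    fixture: str | None = None
    tf_pattern: int | None = None  # canonical TF topology 1-4
    tf_regions: tuple[int, int] | None = None  # (count, span) custom pattern
    tf_concentration: float | None = None  # percent of linker beads
    lh_density: float = 0.0
    lh_mode: str = "uniform"
    lh_positions: tuple[int, ...] | None = None
    acetyl_islands: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.builder not in ("uniform", "lifelike", "gene", "fixture"):
            raise ValueError(f"unknown builder {self.builder!r}")
        if self.builder == "fixture" and not self.fixture:
            raise ValueError("builder 'fixture' requires a fixture name")
        if self.n_cores < 1:
            raise ValueError(f"n_cores must be >= 1, got {self.n_cores}")
        if self.linker_bp <= 0:
            raise ValueError(f"linker_bp must be > 0, got {self.linker_bp}")
        if self.tf_concentration is not None and not (0 <= self.tf_concentration <= 100):
            raise ValueError("tf_concentration must be in [0, 100]")

    def build(self):
        from . import topology as tb
        from .fixtures import make_fixture

        if self.builder == "fixture":
            topo, _ = make_fixture(self.fixture, seed=self.seed)
        elif self.builder == "uniform":
            topo = tb.build_uniform_fiber(self.n_cores, self.linker_bp)
        elif self.builder == "lifelike":
            topo = tb.build_lifelike_fiber(self.n_cores, seed=self.seed)
        else:
            raise ConfigError("gene fibers are built via tracks; use the fixture builder")
        if self.tf_pattern is not None:
            topo = tb.apply_tf_topology(topo, tb.TFTopologySpec.pattern(self.tf_pattern))
        elif self.tf_regions is not None:
            count, span = self.tf_regions
            topo = tb.apply_tf_topology(
                topo, tb.TFTopologySpec(count, span, "evenly")
            )
        elif self.tf_concentration is not None:
            topo = tb.set_tf_concentration(topo, self.tf_concentration, seed=self.seed)
        if self.lh_positions is not None:
            topo = tb.place_linker_histones(
                topo, 0.0, mode="explicit", positions=list(self.lh_positions)
            )
        elif self.lh_density > 0:
            topo = tb.place_linker_histones(
                topo, self.lh_density, mode=self.lh_mode, seed=self.seed
            )
        if self.acetyl_islands:
            topo = tb.mark_acetylation(topo, list(self.acetyl_islands))
        return topo


@dataclass(frozen=True)
class MCConfig:
    """Replica schedule and move-set overrides."""

    n_replicas: int = 1
    n_steps: int = 1_000_000
    save_every: int = 100_000
    base_seed: int = 1
    moves: MoveSet = field(default_factory=MoveSet)

    def plan(self):
        from .sampler import ReplicaPlan

        return ReplicaPlan.from_base_seed(
            self.n_replicas, self.n_steps, self.save_every, self.base_seed
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Requested analysis operations and their parameters."""

    ops: tuple[str, ...] = ("packing", "sed", "rg", "map")
    ensemble_tail_steps: int | None = None
    contact_cutoff_nm: float = 2.0
    eps: float = 2.0
    minpoints: int = 5
    alpha: float = 100.0
    promoter_cores: tuple[int, int] | None = None  # 1-based inclusive

    _KNOWN_OPS = ("packing", "sed", "rg", "map", "decay", "domains", "promoter",
                  "convergence", "tf")

    def __post_init__(self) -> None:
        bad = set(self.ops) - set(self._KNOWN_OPS)
        if bad:
            raise ValueError(f"unknown analysis op(s): {', '.join(sorted(bad))}")


@dataclass(frozen=True)
class RunConfig:
    """Validated, schema-versioned run configuration."""

    system: SystemConfig = field(default_factory=SystemConfig)
    forcefield: ForceField = field(default_factory=ForceField)
    restraints: RestraintParams = field(default_factory=RestraintParams)
    mc: MCConfig = field(default_factory=MCConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "out"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        version = doc.pop("schema", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema {version!r}")
        _take(doc, "<root>", {"system", "forcefield", "restraints", "mc",
                              "analysis", "output_dir"})

        def tup(x):
            return tuple(tuple(i) if isinstance(i, list) else i for i in x)

        sys_d = dict(doc.get("system", {}))
        for key in ("tf_regions", "lh_positions", "acetyl_islands"):
            if key in sys_d and sys_d[key] is not None:
                sys_d[key] = tup(sys_d[key])
        mc_d = dict(doc.get("mc", {}))
        if "moves" in mc_d:
            mc_d["moves"] = _build_dataclass(MoveSet, dict(mc_d["moves"]), "mc.moves")
        an_d = dict(doc.get("analysis", {}))
        for key in ("ops", "promoter_cores"):
            if key in an_d and an_d[key] is not None:
                an_d[key] = tuple(an_d[key])
        return cls(
            system=_build_dataclass(SystemConfig, sys_d, "system"),
            forcefield=_build_dataclass(ForceField, dict(doc.get("forcefield", {})), "forcefield"),
            restraints=_build_dataclass(
                RestraintParams, dict(doc.get("restraints", {})), "restraints"
            ),
            mc=_build_dataclass(MCConfig, mc_d, "mc"),
            analysis=_build_dataclass(AnalysisConfig, an_d, "analysis"),
            output_dir=str(doc.get("output_dir", "out")),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema"] = SCHEMA_VERSION
        d["output_dir"] = self.output_dir
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; defaults applied per section."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(doc)
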