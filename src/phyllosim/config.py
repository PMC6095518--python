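"""Run configuration: one YAML file drives a complete simulation.

The config groups the grid, the chemical (BVAM) parameters, the mechanical
parameters, the two-time-scale scheduler and the detection knobs.  Every
physical default is the published value where one exists; ``chem.eta`` has
no default and must always be supplied because it encodes the domain size
and thereby selects the pattern symmetry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chemistry import BVAMParams
from .energy import MechParams
from .grid import GridSpec

__all__ = ["ScheduleParams", "DetectionParams", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ScheduleParams:
    """Two-time-scale scheduler.

    Each outer cycle runs ``n_chem`` chemical steps at ``dt_chem`` (the
    Turing "pulse") followed by ``n_mech`` mechanical steps at ``dt_mech``;
    the stress tensor is refreshed every ``stress_every`` mechanical steps.
    The outer-cycle counter is the trajectory's time axis T.
    """

    n_chem: int = 100
    n_mech: int = 1000
    n_cycles: int = 200
    stress_every: int = 10
    snapshot_every: int = 0  # 0: keep only the final state
    stop_after_generations: int = 0  # 0: run all cycles
    noise_amplitude: float = 0.1
    on_divergence: str = "raise"  # or "truncate": keep the last good cycle

    def __post_init__(self) -> None:
        if min(self.n_chem, self.n_mech, self.n_cycles, self.stress_every) < 1:
            raise ValueError("scheduler counts must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.on_divergence not in ("raise", "truncate"):
            raise ValueError("on_divergence must be 'raise' or 'truncate'")


@dataclass(frozen=True)
class DetectionParams:
    """Primordium detection and fixation knobs (artifact definitions)."""

    n_sigma: float = 2.0  # adaptive threshold: mean + n_sigma * SD
    u_floor: float = 0.2  # absolute threshold floor (above seed noise,
    #                        well below the saturated pattern amplitude ~1)
    tau: int = 5  # persistence (cycles) before fixation
    track_radius: float = 3.0  # candidate matching radius (grid units)
    merge_radius: float = 3.0  # cluster-fragment merge radius (grid units)
    generation_window: int = 25  # cycles grouping births into one whorl
    stationarity_tol: float = 0.05  # relative std change marking a settled pulse
    #   (exponential pattern growth changes std by >~10% per cycle; the
    #    plateau, even under mechanical perturbation, stays below this)
    min_std: float = 0.1  # pattern amplitude below which nothing is detected

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("persistence tau must be >= 1")


_RANGES = {
    ("chem", "c"): (0.0, 0.57),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a trajectory bit-for-bit."""

    chem: BVAMParams
    grid: GridSpec = field(default_factory=GridSpec)
    mech: MechParams = field(default_factory=MechParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        for (group, name), (lo, hi) in _RANGES.items():
            val = getattr(getattr(self, group), name)
            if not (lo <= val <= hi):
                raise ValueError(f"{group}.{name}={val} outside [{lo}, {hi}]")

    def replace(self, **dotted) -> "RunConfig":
        """Return a copy with dotted attributes replaced, e.g. ``chem.eta``."""
        groups: dict[str, dict] = {}
        top: dict = {}
        for key, value in dotted.items():
            if "." in key:
                g, name = key.split(".", 1)
                groups.setdefault(g, {})[name] = value
            else:
                top[key] = value
        updates = dict(top)
        for g, kv in groups.items():
            updates[g] = dataclasses.replace(getattr(self, g), **kv)
        return dataclasses.replace(self, **updates)


_GROUPS = {
    "grid": GridSpec,
    "chem": BVAMParams,
    "mech": MechParams,
    "schedule": ScheduleParams,
    "detection": DetectionParams,
}


def _build_group(cls, data: dict, label: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in '{label}': {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; defaults fill every omitted key."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known_top = set(_GROUPS) | {"seed", "outdir"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    chem_data = dict(raw.get("chem", {}))
    if "eta" not in chem_data:
        raise ValueError("chem.eta must be supplied (it has no printed default)")
    kwargs = {
        name: _build_group(cls, dict(raw.get(name, {})), name)
        for name, cls in _GROUPS.items()
        if name != "chem"
    }
    kwargs["chem"] = _build_group(BVAMParams, chem_data, "chem")
    return RunConfig(seed=int(raw.get("seed", 0)), outdir=str(raw.get("outdir", ".")),
                     **kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML (lossless round trip with :func:`load_config`)."""
    data = {
        name: dataclasses.asdict(getattr(config, name)) for name in _GROUPS
    }
    data["seed"] = config.seed
    data["outdir"] = config.outdir
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
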