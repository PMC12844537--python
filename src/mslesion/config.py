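"""Simulation configuration, spatial region map, and relapse schedule.

The model lattice is a 2-D grid of ``lattice_width`` columns by
``lattice_height`` rows, split left-to-right into three vertical bands:
peripheral blood, perivascular space (PVS), and parenchyma.  Columns and
rows are 1-based throughout the public API, with column 1 at the left
(blood) edge and rows wrapping periodically top-to-bottom.

All tunable model parameters live in a single validated
:class:`SimulationConfig` record that round-trips through a flat YAML
file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import yaml

__all__ = [
    "SimulationConfig",
    "RegionMap",
    "ConfigurationError",
    "LatticePartitionError",
    "RateBoundsError",
    "ThresholdOrderError",
    "BlockDivisibilityError",
    "BiasRangeError",
    "ScheduleError",
    "UnknownKeyError",
    "build_region_map",
    "relapse_active",
    "validate_config",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Base class for invalid simulation configurations."""


class LatticePartitionError(ConfigurationError):
    """Region widths do not partition the lattice columns."""


class RateBoundsError(ConfigurationError):
    """A probability or rate parameter lies outside its valid range."""


class ThresholdOrderError(ConfigurationError):
    """Stress thresholds violate 1 <= omega <= lambda <= block area."""


class BlockDivisibilityError(ConfigurationError):
    """Parenchyma dimensions are not multiples of the oligodendrocyte block side."""


class BiasRangeError(ConfigurationError):
    """Chemotactic bias magnitude outside its supported range."""


class ScheduleError(ConfigurationError):
    """Relapse schedule or step counts are inconsistent."""


class UnknownKeyError(ConfigurationError):
    """A configuration file contains a key that is not a model parameter."""


@dataclass
class SimulationConfig:
    """Every model parameter in one validated record.

    Geometry is in lattice units of ``delta`` micrometres; time is in steps
    of ``tau`` minutes (72 steps per day at the default tau=20).

    Parameters
    ----------
    rho_R, rho_NR
        Per-blood-site, per-step primed T-cell spawn probability during and
        outside relapses.  Defaults reproduce a mean influx of 2.25 (relapse)
        and 0.18 (remission) new primed T cells per step over the 900 blood
        sites.
    rho_d
        Per-step death probability of primed and reactivated T cells,
        derived from a 48 h cytotoxic-T-cell half-life (0.35/day at tau=20).
    b_R, b_L
        Blood-brain-barrier crossing probabilities for rightward (blood to
        PVS) and leftward movement.  b_L = 0 makes the barrier one-way.
    beta, k
        Maximum chemotactic bias magnitude and its spatial decay constant
        (per lattice unit): s_bias = beta * exp(-k * D) for a reactivated
        T cell at Euclidean distance D from the nearest degradable myelin.
    n_myelin_states
        Number S of discrete myelin states; S is fully intact, 1 fully
        degraded.
    repair_delay
        Steps W of reactivated-T-cell non-occupation required per one-state
        repair increment.
    omega, lambda_
        Oligodendrocyte stress thresholds on the count sigma of fully
        degraded sites in a 5x5 block: at sigma >= omega the cell stops
        myelinating, at sigma >= lambda it undergoes apoptosis.
    """

    lattice_width: int = 108
    lattice_height: int = 300
    delta: float = 10.0
    blood_width: int = 3
    pvs_width: int = 5
    parenchyma_width: int = 100
    tau: float = 20.0
    n_steps: int = 21600
    rho_R: float = 0.0025
    rho_NR: float = 0.0002
    rho_d: float = 0.0049
    b_R: float = 0.1
    b_L: float = 0.0
    beta: float = 0.5
    k: float = 0.033
    n_myelin_states: int = 4
    repair_delay: int = 16
    omega: int = 10
    lambda_: int = 14
    oligo_block: int = 5
    pvm_count: int = 45
    relapse_onsets: tuple = (0, 100, 200)
    relapse_duration_days: float = 28.0
    seed: int = 0
    # extensions beyond the core model, exposed as explicit toggles
    clamp_probabilities: bool = True
    per_agent_damage: bool = False
    # chemotactic targets: fully intact sites only (True) or any site with
    # remaining health (False)
    bias_target_intact: bool = True

    # -- derived quantities ------------------------------------------------
    @property
    def steps_per_day(self) -> int:
        return round(1440.0 / self.tau)

    @property
    def n_days(self) -> float:
        return self.n_steps / self.steps_per_day

    @property
    def relapse_steps(self) -> list[tuple[int, int]]:
        """Half-open step windows [start, stop) of each relapse."""
        spd = self.steps_per_day
        dur = int(round(self.relapse_duration_days * spd))
        return [(int(d * spd), int(d * spd) + dur) for d in self.relapse_onsets]

    def replace(self, **kwargs) -> "SimulationConfig":
        return validate_config(dataclasses.replace(self, **kwargs))


@dataclass(frozen=True)
class RegionMap:
    """Per-column classification of the lattice into blood / PVS / parenchyma.

    Columns are 1-based.  ``bbb_column_pair`` is the (blood, PVS) column pair
    across which the blood-brain barrier sits; ``pvs_parenchyma_pair`` the
    (PVS, parenchyma) interface pair.
    """

    lattice_width: int
    lattice_height: int
    blood_columns: range
    pvs_columns: range
    parenchyma_columns: range
    bbb_column_pair: tuple[int, int]
    pvs_parenchyma_pair: tuple[int, int]

    def region_of_column(self, col: int) -> str:
        if col in self.blood_columns:
            return "blood"
        if col in self.pvs_columns:
            return "pvs"
        if col in self.parenchyma_columns:
            return "parenchyma"
        raise ValueError(f"column {col} outside lattice")

    @property
    def n_blood_sites(self) -> int:
        return len(self.blood_columns) * self.lattice_height

    @property
    def n_pvs_sites(self) -> int:
        return len(self.pvs_columns) * self.lattice_height

    @property
    def n_parenchyma_sites(self) -> int:
        return len(self.parenchyma_columns) * self.lattice_height


def validate_config(config: SimulationConfig) -> SimulationConfig:
    """Check every invariant; return the (unchanged) config on success.

    Each violated invariant raises a distinct :class:`ConfigurationError`
    subclass so callers can report precisely what is wrong.
    """
    c = config
    if c.blood_width + c.pvs_width + c.parenchyma_width != c.lattice_width:
        raise LatticePartitionError(
            f"blood({c.blood_width}) + pvs({c.pvs_width}) + "
            f"parenchyma({c.parenchyma_width}) != lattice_width({c.lattice_width})"
        )
    if min(c.blood_width, c.pvs_width, c.parenchyma_width, c.lattice_height) < 1:
        raise LatticePartitionError("region widths and height must be positive")
    for name in ("rho_R", "rho_NR", "rho_d", "b_L"):
        v = getattr(c, name)
        if not 0.0 <= v <= 1.0:
            raise RateBoundsError(f"{name}={v} outside [0, 1]")
    if not 0.0 < c.b_R <= 1.0:
        raise RateBoundsError(f"b_R={c.b_R} outside (0, 1]")
    if c.rho_NR > c.rho_R:
        raise RateBoundsError(f"rho_NR={c.rho_NR} exceeds rho_R={c.rho_R}")
    block_area = c.oligo_block**2
    if not 1 <= c.omega <= c.lambda_ <= block_area:
        raise ThresholdOrderError(
            f"need 1 <= omega({c.omega}) <= lambda({c.lambda_}) <= {block_area}"
        )
    if c.parenchyma_width % c.oligo_block or c.lattice_height % c.oligo_block:
        raise BlockDivisibilityError(
            f"parenchyma {c.parenchyma_width}x{c.lattice_height} not a multiple "
            f"of block side {c.oligo_block}"
        )
    if not 0.0 <= c.beta <= 0.75:
        raise BiasRangeError(f"beta={c.beta} outside [0, 0.75]")
    if c.beta > 0.5 and not c.clamp_probabilities:
        raise BiasRangeError(
            "beta > 0.5 can produce negative movement probabilities; "
            "enable clamp_probabilities"
        )
    if c.k <= 0:
        raise BiasRangeError(f"bias decay constant k={c.k} must be > 0")
    if c.n_myelin_states < 2:
        raise ConfigurationError("n_myelin_states must be >= 2")
    if c.repair_delay < 1:
        raise ConfigurationError("repair_delay must be >= 1")
    if c.n_steps < 0:
        raise ScheduleError("n_steps must be >= 0")
    if c.pvm_count < 0 or c.pvm_count > c.pvs_width * c.lattice_height:
        raise ConfigurationError(
            f"pvm_count={c.pvm_count} exceeds PVS capacity "
            f"{c.pvs_width * c.lattice_height}"
        )
    if not math.isclose(1440.0 / c.tau, round(1440.0 / c.tau)):
        raise ScheduleError(f"tau={c.tau} min must divide a day evenly")
    if c.relapse_duration_days < 0 or any(d < 0 for d in c.relapse_onsets):
        raise ScheduleError("relapse onsets and duration must be non-negative")
    return c


def build_region_map(config: SimulationConfig) -> RegionMap:
    """Partition lattice columns into blood | PVS | parenchyma, left to right.

    With the default geometry: columns 1-3 blood, 4-8 PVS, 9-108 parenchyma.
    """
    c = validate_config(config)
    b, p = c.blood_width, c.pvs_width
    return RegionMap(
        lattice_width=c.lattice_width,
        lattice_height=c.lattice_height,
        blood_columns=range(1, b + 1),
        pvs_columns=range(b + 1, b + p + 1),
        parenchyma_columns=range(b + p + 1, c.lattice_width + 1),
        bbb_column_pair=(b, b + 1),
        pvs_parenchyma_pair=(b + p, b + p + 1),
    )


def relapse_active(step: int, config: SimulationConfig) -> bool:
    """True iff ``step`` falls inside a half-open relapse window.

    Each relapse spans days [onset, onset + relapse_duration_days); at the
    default schedule that is three 4-week windows starting on days 0, 100
    and 200.
    """
    if not 0 <= step < max(config.n_steps, 1):
        raise ValueError(f"step {step} outside [0, {config.n_steps})")
    return any(start <= step < stop for start, stop in config.relapse_steps)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def save_config(config: SimulationConfig, path) -> None:
    """Serialize to a flat YAML key-value file."""
    data = dataclasses.asdict(config)
    data["relapse_onsets"] = list(config.relapse_onsets)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    """Parse and validate a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of parameters")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise UnknownKeyError(f"unknown configuration keys: {sorted(unknown)}")
    if "relapse_onsets" in data:
        data["relapse_onsets"] = tuple(data["relapse_onsets"])
    return validate_config(SimulationConfig(**data))
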