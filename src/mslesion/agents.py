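"""The three mobile immune-cell populations and their update rules.

Primed T cells spawn stochastically in the peripheral blood, random-walk,
and cross the blood-brain barrier into the perivascular space (PVS) with
probability ``b_R`` per rightward attempt.  Perivascular macrophages (PVMs)
random-walk inside the PVS and convert co-located primed T cells into
reactivated T cells (antigen presentation).  Reactivated T cells seek
myelin by a biased random walk whose bias decays exponentially with the
Euclidean distance to the nearest degradable myelin site, and degrade the
site they occupy until it is fully demyelinated.

Positions are 1-based ``(col, row)`` lattice coordinates.  Movement uses
the Von Neumann neighbourhood; one movement event is imposed per cell per
step (a failed barrier crossing consumes the move).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from ._kernels import nearest_eligible
from .config import RegionMap, SimulationConfig
from .myelin import MyelinField

__all__ = [
    "AgentPopulation",
    "BiasResult",
    "DIRECTIONS",
    "spawn_primed",
    "seed_pvms",
    "unbiased_step",
    "nearest_eligible_myelin",
    "biased_move_probs",
    "attempt_bbb_cross",
    "apply_boundaries",
    "antigen_presentation",
    "apply_death",
    "death_probability",
    "REMOVE",
]

#: direction order used everywhere: north (row-1), south (row+1),
#: east (col+1), west (col-1)
DIRECTIONS = ("N", "S", "E", "W")
_DROW = np.array([-1, 1, 0, 0], dtype=np.int64)
_DCOL = np.array([0, 0, 1, -1], dtype=np.int64)

#: sentinel returned by :func:`apply_boundaries` for right-edge removal
REMOVE = None


@dataclass
class AgentPopulation:
    """Positions of the three mobile populations as (n, 2) ``(col, row)`` arrays."""

    primed: np.ndarray = dfield(default_factory=lambda: np.empty((0, 2), np.int64))
    pvms: np.ndarray = dfield(default_factory=lambda: np.empty((0, 2), np.int64))
    reactivated: np.ndarray = dfield(default_factory=lambda: np.empty((0, 2), np.int64))
    engaged: np.ndarray = dfield(default_factory=lambda: np.empty(0, bool))

    def counts(self) -> tuple[int, int, int]:
        return len(self.primed), len(self.pvms), len(self.reactivated)


@dataclass(frozen=True)
class BiasResult:
    """Chemotactic pull toward the nearest degradable myelin site.

    ``s_bias = beta * exp(-k * distance)`` is the probability mass shifted
    toward the target; it never exceeds ``beta``.
    """

    s_bias: float
    target: tuple[int, int]   # (col, row) of the nearest eligible site
    distance: float           # Euclidean lattice units


def spawn_primed(config: SimulationConfig, relapse_flag: bool,
                 rng: np.random.Generator) -> np.ndarray:
    """Independent per-blood-site Bernoulli spawns of new primed T cells.

    The spawn probability is ``rho_R`` during a relapse and ``rho_NR``
    otherwise, giving mean influxes of 2.25 and 0.18 cells per step over
    the default 900 blood sites.  Returns an (n, 2) array of (col, row).
    """
    rho = config.rho_R if relapse_flag else config.rho_NR
    n_sites = config.blood_width * config.lattice_height
    hits = np.nonzero(rng.random(n_sites) < rho)[0]
    # site index = (col-1) * height + (row-1), column-major over blood columns
    cols = hits // config.lattice_height + 1
    rows = hits % config.lattice_height + 1
    return np.column_stack([cols, rows])


def seed_pvms(config: SimulationConfig, region: RegionMap,
              rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of ``pvm_count`` distinct PVS sites."""
    n_sites = region.n_pvs_sites
    if config.pvm_count > n_sites:
        raise ValueError(f"pvm_count={config.pvm_count} > {n_sites} PVS sites")
    picks = rng.choice(n_sites, size=config.pvm_count, replace=False)
    cols = picks // region.lattice_height + region.pvs_columns.start
    rows = picks % region.lattice_height + 1
    return np.column_stack([cols, rows])


def unbiased_step(pos: tuple[int, int], rng: np.random.Generator) -> tuple[int, int]:
    """Propose one Von Neumann neighbour, each with probability 0.25."""
    d = int(rng.integers(4))
    return pos[0] + int(_DCOL[d]), pos[1] + int(_DROW[d])


def nearest_eligible_myelin(pos: tuple[int, int], field: MyelinField,
                            beta: float = 0.5, k: float = 0.033,
                            eligible_mask: np.ndarray | None = None,
                            ) -> BiasResult | None:
    """Locate the nearest myelin site with remaining health (state >= 2).

    Ties in Euclidean distance are broken by lowest row, then lowest
    column.  Returns ``None`` when no degradable myelin remains, in which
    case movement falls back to the unbiased walk.  Fully degraded sites
    (including whole apoptotic blocks) are never targets.
    """
    if eligible_mask is None:
        eligible_mask = field.state >= 2
    col, row = pos
    tr, tc, d2, found = nearest_eligible(
        np.array([row - 1]), np.array([col - field.col_offset]), eligible_mask)
    if not found[0]:
        return None
    dist = math.sqrt(float(d2[0]))
    return BiasResult(
        s_bias=beta * math.exp(-k * dist),
        target=(int(tc[0]) + field.col_offset, int(tr[0]) + 1),
        distance=dist,
    )


def biased_move_probs(pos: tuple[int, int], bias: BiasResult,
                      clamp: bool = True) -> np.ndarray:
    """Movement probabilities (N, S, E, W) under chemotactic bias.

    The two directions pointing toward the target gain
    ``s_bias * |component| / (|dx| + |dy|)`` on top of the baseline 0.25;
    the two opposite directions lose ``s_bias / 2`` each, so the four
    probabilities sum to one.  When the target is axis-aligned the
    zero-weight favoured axis keeps its baseline 0.25 (the favoured
    direction of a zero component is taken to be north / west).  For
    ``s_bias > 0.5`` the opposing probabilities would go negative; with
    ``clamp`` they are clamped at zero and renormalised.
    """
    col, row = pos
    tcol, trow = bias.target
    dx, dy = tcol - col, trow - row
    if dx == 0 and dy == 0:
        raise ValueError("bias target coincides with the agent position")
    adx, ady = abs(dx), abs(dy)
    tot = adx + ady
    s = bias.s_bias
    p = np.full(4, 0.25)
    # x axis: favoured direction east if dx > 0, else west (west on ties)
    fav_x, unfav_x = (2, 3) if dx > 0 else (3, 2)
    fav_y, unfav_y = (1, 0) if dy > 0 else (0, 1)  # south if dy > 0 else north
    p[fav_x] += s * adx / tot
    p[fav_y] += s * ady / tot
    p[unfav_x] -= s / 2
    p[unfav_y] -= s / 2
    if clamp:
        p = np.maximum(p, 0.0)
        p /= p.sum()
    return p


def attempt_bbb_cross(direction: str, config: SimulationConfig,
                      rng: np.random.Generator) -> bool:
    """Succeeds with probability ``b_R`` eastward, ``b_L`` westward.

    With the default ``b_L = 0`` the barrier is one-way: cells that entered
    the CNS never return to the blood.
    """
    if direction not in ("E", "W"):
        raise ValueError("barrier crossings are horizontal (E or W)")
    b = config.b_R if direction == "E" else config.b_L
    return bool(rng.random() < b)


def apply_boundaries(pos: tuple[int, int], proposed: tuple[int, int],
                     agent_type: str, region: RegionMap):
    """Resolve a proposed move against the domain boundaries.

    Top/bottom wrap periodically for every agent.  The left edge reflects
    (the agent keeps its position); the right edge is absorbing and returns
    :data:`REMOVE`.  PVMs are confined to the PVS: proposals into blood or
    parenchyma leave them in place.  T cells cross the PVS-parenchyma
    interface freely.  Blood-brain-barrier crossings are stochastic and are
    resolved separately by :func:`attempt_bbb_cross`.
    """
    col, row = proposed
    h = region.lattice_height
    row = (row - 1) % h + 1
    if agent_type == "pvm":
        if col not in region.pvs_columns:
            return pos
        return (col, row)
    if col < 1:
        return (pos[0], pos[1])
    if col > region.lattice_width:
        return REMOVE
    return (col, row)


def antigen_presentation(population: AgentPopulation) -> AgentPopulation:
    """Convert primed T cells co-located with a PVM into reactivated T cells.

    Every primed T cell standing on a site that also holds at least one PVM
    is removed and replaced by a reactivated T cell at the same site (one
    conversion per primed cell; PVMs persist and site occupation is not
    mutually exclusive).  Newly created cells start unengaged.
    """
    if len(population.primed) == 0 or len(population.pvms) == 0:
        return population
    pvm_keys = np.unique(population.pvms[:, 0] * 100000 + population.pvms[:, 1])
    primed_keys = population.primed[:, 0] * 100000 + population.primed[:, 1]
    hit = np.isin(primed_keys, pvm_keys)
    if not hit.any():
        return population
    converted = population.primed[hit]
    population.primed = population.primed[~hit]
    population.reactivated = np.concatenate([population.reactivated, converted])
    population.engaged = np.concatenate(
        [population.engaged, np.zeros(len(converted), bool)])
    return population


def apply_death(population: AgentPopulation, config: SimulationConfig,
                rng: np.random.Generator) -> AgentPopulation:
    """Remove each primed and reactivated T cell with probability ``rho_d``.

    PVMs are a stable population and never die.  At the default
    ``rho_d = 0.0049`` a cohort halves in roughly 144 steps (48 h).
    """
    n_p = len(population.primed)
    keep_p = rng.random(n_p) >= config.rho_d
    population.primed = population.primed[keep_p]
    n_r = len(population.reactivated)
    keep_r = rng.random(n_r) >= config.rho_d
    population.reactivated = population.reactivated[keep_r]
    population.engaged = population.engaged[keep_r]
    return population


def death_probability(decay_per_day: float = 0.35, tau: float = 20.0) -> float:
    """Per-step death probability from a first-order decay rate.

    The 48 h cytotoxic-T-cell half-life gives ln(2)/2 = 0.35/day, which at
    tau = 20 min (72 steps/day) yields 0.35/72 = 0.0049 per step.
    """
    return decay_per_day * tau / 1440.0
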