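"""Simulation engine: one fixed-order step, full runs, and metrics recording.

Each step applies, in order: (1) primed T-cell spawning (relapse-aware);
(2) synchronous movement of primed T cells, PVMs and unengaged reactivated
T cells, with blood-brain-barrier and boundary rules; (3) antigen
presentation; (4) myelin degradation and (re-)engagement; (5) repair;
(6) oligodendrocyte stress updates (apoptosis zeroing); (7) T-cell death;
(8) metrics.  Chemotactic bias switches on globally at the first recorded
myelin damage event and stays on.

A single seeded random stream drives a run; identical (config, plan, seed)
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np
import pandas as pd

from . import myelin as my
from .agents import AgentPopulation, seed_pvms
from . import _kernels as k
from .config import RegionMap, SimulationConfig, build_region_map, relapse_active

__all__ = ["SimulationState", "MetricsSeries", "init_state", "advance",
           "run_simulation"]

_METRIC_COLUMNS = (
    "primed", "pvms", "reactivated", "reactivated_parenchyma",
    "intact_fraction", "partial_fraction", "damaged_fraction",
    "myelinating_fraction", "nonmyelinating_fraction", "apoptotic_fraction",
)


@dataclass
class SimulationState:
    """Live state of one replicate, including post-intervention parameters."""

    config: SimulationConfig
    region: RegionMap
    population: AgentPopulation
    myelin: my.MyelinField
    oligos: my.OligoGrid
    rng: np.random.Generator
    step: int = 0
    bias_enabled: bool = False
    # live parameters (treatments overwrite these, not the config)
    b_R: float = 0.0
    b_L: float = 0.0
    omega: int = 0
    lambda_: int = 0
    last_events: dict = dfield(default_factory=dict)
    _occ_scratch: Optional[np.ndarray] = None  # reusable occupancy buffer
    _counts: Optional[tuple] = None            # kernel site/status tallies


@dataclass
class MetricsSeries:
    """Per-step population counts and state fractions (row 0 = initial state)."""

    data: np.ndarray            # (n_steps + 1, len(_METRIC_COLUMNS))
    steps_per_day: int
    columns: tuple = _METRIC_COLUMNS
    block_time_in_state: Optional[np.ndarray] = None   # (3, Hb, Wb) steps

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[:, self.columns.index(name)]

    @property
    def day(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) / self.steps_per_day

    def at_day(self, name: str, day: float) -> float:
        """Value of a metric at the start of the given day (clipped to the end)."""
        i = min(int(round(day * self.steps_per_day)), self.data.shape[0] - 1)
        return float(self[name][i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.columns))
        df.insert(0, "step", np.arange(len(df)))
        df.insert(1, "day", self.day)
        return df


def init_state(config: SimulationConfig, seed=None) -> SimulationState:
    """Fresh state: intact myelin, seeded PVMs, no T cells yet."""
    region = build_region_map(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    field, grid = my.init_fields(config)
    pop = AgentPopulation(pvms=seed_pvms(config, region, rng))
    return SimulationState(
        config=config, region=region, population=pop, myelin=field,
        oligos=grid, rng=rng, b_R=config.b_R, b_L=config.b_L,
        omega=config.omega, lambda_=config.lambda_,
        _occ_scratch=np.zeros(field.state.shape, bool),
    )


def spawn_primed(cfg: SimulationConfig, relapse: bool,
                 rng: np.random.Generator) -> np.ndarray:
    """Engine-internal spawn (same Bernoulli scheme as agents.spawn_primed)."""
    rho = cfg.rho_R if relapse else cfg.rho_NR
    hits = np.nonzero(rng.random(cfg.blood_width * cfg.lattice_height) < rho)[0]
    out = np.empty((hits.size, 2), np.int64)
    out[:, 0] = hits // cfg.lattice_height + 1
    out[:, 1] = hits % cfg.lattice_height + 1
    return out


def advance(state: SimulationState, config: SimulationConfig | None = None
            ) -> SimulationState:
    """Advance the simulation by one step (sub-step order fixed; see module doc)."""
    cfg = config or state.config
    pop, region, rng = state.population, state.region, state.rng
    field, grid = state.myelin, state.oligos
    h, w = region.lattice_height, region.lattice_width
    bbb_blood, bbb_pvs = region.bbb_column_pair
    events = {"spawned": 0, "converted": 0, "primed_died": 0,
              "reactivated_died": 0, "primed_removed": 0,
              "reactivated_removed": 0, "damage_events": 0, "repair_events": 0}

    # (1) spawn primed T cells in the peripheral blood
    spawned = spawn_primed(cfg, relapse_active(state.step, cfg), rng)
    events["spawned"] = len(spawned)
    if len(spawned):
        pop.primed = np.concatenate([pop.primed, spawned])

    # (2) synchronous movement proposals, resolved independently; one
    # uniform per agent covers any barrier attempt that move makes
    n = len(pop.primed)
    if n:
        dirs = rng.integers(0, 4, n)
        u = rng.random(n)
        m = k.move_tcells(pop.primed, dirs, u, state.b_R, state.b_L,
                          h, w, bbb_blood, bbb_pvs)
        events["primed_removed"] = n - m
        pop.primed = pop.primed[:m]
    if len(pop.pvms):
        dirs = rng.integers(0, 4, len(pop.pvms))
        k.move_pvms(pop.pvms, dirs, h,
                    region.pvs_columns.start, region.pvs_columns[-1])
    n_free = int((~pop.engaged).sum())
    if n_free:
        engaged_pos = pop.reactivated[pop.engaged]
        moving = pop.reactivated[~pop.engaged]
        u_dir = rng.random(n_free)
        if state.bias_enabled:
            off = field.col_offset
            eligible = (field.state == field.n_states if cfg.bias_target_intact
                        else field.state >= 2)
            tr, tc, d2, found = k.nearest_eligible(
                moving[:, 1] - 1, moving[:, 0] - off, eligible)
            dirs = k.biased_directions(moving, tr, tc, d2, found, u_dir,
                                       cfg.beta, cfg.k,
                                       cfg.clamp_probabilities, off)
        else:
            dirs = np.minimum((u_dir * 4.0).astype(np.int64), 3)
        u = rng.random(n_free)
        m = k.move_tcells(moving, dirs, u, state.b_R, state.b_L,
                          h, w, bbb_blood, bbb_pvs)
        events["reactivated_removed"] = n_free - m
        pop.reactivated = np.concatenate([engaged_pos, moving[:m]])
        pop.engaged = np.zeros(len(pop.reactivated), bool)
        pop.engaged[:len(engaged_pos)] = True

    # (3) antigen presentation at sites shared by a primed T cell and a PVM
    if len(pop.primed) and len(pop.pvms):
        hit = k.convert_primed(pop.primed, pop.pvms,
                               region.pvs_columns.start,
                               region.pvs_columns[-1], h)
        n_conv = int(hit.sum())
        if n_conv:
            events["converted"] = n_conv
            pop.reactivated = np.concatenate([pop.reactivated, pop.primed[hit]])
            pop.engaged = np.concatenate([pop.engaged, np.zeros(n_conv, bool)])
            pop.primed = pop.primed[~hit]

    # (4-6) fused parenchyma sweep: degradation at occupied sites, delayed
    # repair, stress recomputation and one-way status transitions
    par_start = region.pvs_parenchyma_pair[1]
    rc, rr = pop.reactivated[:, 0], pop.reactivated[:, 1]
    in_par = rc >= par_start
    fr, fc = rr[in_par] - 1, rc[in_par] - field.col_offset
    (events["damage_events"], events["repair_events"], intact, damaged,
     n_my, n_nm, n_ap, _) = k.field_step(
        field.state, field.repair_counter, grid.status, state._occ_scratch,
        fr, fc, grid.block, cfg.repair_delay, field.n_states,
        cfg.per_agent_damage, state.omega, state.lambda_)
    if events["damage_events"] and not state.bias_enabled:
        state.bias_enabled = True
    new_engaged = np.zeros(len(pop.reactivated), bool)
    new_engaged[in_par] = field.state[fr, fc] >= 2
    pop.engaged = new_engaged
    state._counts = (intact, damaged, n_my, n_nm, n_ap)
    for s in range(3):
        grid.time_in_state[s] += grid.status == s

    # (7) death of primed and reactivated T cells
    keep = rng.random(len(pop.primed)) >= cfg.rho_d
    events["primed_died"] = int((~keep).sum())
    pop.primed = pop.primed[keep]
    keep = rng.random(len(pop.reactivated)) >= cfg.rho_d
    events["reactivated_died"] = int((~keep).sum())
    pop.reactivated = pop.reactivated[keep]
    pop.engaged = pop.engaged[keep]

    state.step += 1
    state.last_events = events
    return state


def _record(state: SimulationState, out: np.ndarray) -> None:
    pop, field, grid = state.population, state.myelin, state.oligos
    par_start = state.region.pvs_parenchyma_pair[1]
    n = field.state.size
    nb = grid.n_blocks
    if state._counts is not None:
        intact, damaged, n_my, n_nm, n_ap = state._counts
    else:
        intact = int((field.state == field.n_states).sum())
        damaged = int((field.state == 1).sum())
        n_my, n_nm, n_ap = np.bincount(grid.status.ravel(), minlength=3)
    out[:] = (
        len(pop.primed), len(pop.pvms), len(pop.reactivated),
        int((pop.reactivated[:, 0] >= par_start).sum()),
        intact / n, (n - intact - damaged) / n, damaged / n,
        n_my / nb, n_nm / nb, n_ap / nb,
    )


def run_simulation(config: SimulationConfig, plan=None, seed=None,
                   snapshot_days=()) -> tuple[MetricsSeries, dict]:
    """Run ``n_steps`` steps, applying an optional treatment plan.

    ``plan`` is a :class:`mslesion.treatments.TreatmentPlan` applied at the
    start of its intervention day.  ``snapshot_days`` requests copies of the
    myelin and oligodendrocyte grids at the start of those days (day 0 is
    the initial state).  Returns the metrics series (one row per step plus
    the initial row) and a dict ``{day: (myelin_states, block_status)}``.
    """
    from .treatments import apply_treatment

    state = init_state(config, seed)
    spd = config.steps_per_day
    n = config.n_steps
    data = np.empty((n + 1, len(_METRIC_COLUMNS)))
    snapshot_steps = {int(round(d * spd)): d for d in snapshot_days}
    plan_step = None if plan is None else int(round(plan.intervention_day * spd))
    _record(state, data[0])
    snapshots = {}
    for step in range(n):
        if plan_step == step:
            apply_treatment(state, plan)
        if step in snapshot_steps:
            snapshots[snapshot_steps[step]] = (
                state.myelin.state.copy(), state.oligos.status.copy())
        advance(state, config)
        _record(state, data[state.step])
    if plan_step == n:
        apply_treatment(state, plan)
    if n in snapshot_steps:
        snapshots[snapshot_steps[n]] = (
            state.myelin.state.copy(), state.oligos.status.copy())
    metrics = MetricsSeries(data=data, steps_per_day=spd,
                            block_time_in_state=state.oligos.time_in_state.copy())
    return metrics, snapshots
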