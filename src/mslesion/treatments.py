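"""Treatment scenarios applied at an intervention day.

Three therapeutic levers are modelled, alone and in combination:

* BBB-targeted disease-modifying therapy: reduce the rightward barrier
  permeability ``b_R`` (immediately from day 0, or from the intervention
  day onward).
* Integrated-stress-response resilience: raise the oligodendrocyte stress
  thresholds ``omega`` and ``lambda``.
* Oligodendrocyte re-establishment (stem-cell / OPC therapy): restore a
  fraction of blocks to the myelinating state with fully intact myelin.

Treatments are step changes with no pharmacokinetics; parameters switch
atomically at the start of the intervention day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import myelin as my
from .config import SimulationConfig
from .engine import SimulationState

__all__ = ["TreatmentPlan", "Scenario", "apply_treatment", "scenario_library"]


@dataclass(frozen=True)
class TreatmentPlan:
    """Parameter overrides and/or block restoration at ``intervention_day``.

    ``restore_fraction`` f selects each oligodendrocyte block independently
    with probability f and resets it to myelinating with all sites fully
    intact (f = 1 restores everything).  By default restoration draws over
    all blocks, so an intact block may be refreshed; set
    ``restore_all_blocks=False`` to restore only non-myelinating and
    apoptotic blocks.  ``reevaluate_nonmyelinating`` controls whether
    raising the thresholds lets non-myelinating blocks whose stress is
    below the new omega resume myelinating (apoptosis is always absorbing).
    """

    intervention_day: float = 80.0
    new_b_R: float | None = None
    new_omega: int | None = None
    new_lambda: int | None = None
    restore_fraction: float | None = None
    restore_all_blocks: bool = True
    reevaluate_nonmyelinating: bool = True

    def __post_init__(self):
        if self.new_omega is not None and self.new_lambda is not None:
            if not self.new_omega <= self.new_lambda <= 25:
                raise ValueError(
                    f"need omega({self.new_omega}) <= lambda({self.new_lambda}) <= 25")
        if self.restore_fraction is not None and not 0 <= self.restore_fraction <= 1:
            raise ValueError("restore_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """A named treatment scenario: config overrides plus an optional plan."""

    name: str
    config_overrides: dict
    plan: TreatmentPlan | None

    def configure(self, config: SimulationConfig) -> SimulationConfig:
        return config.replace(**self.config_overrides) if self.config_overrides else config


def apply_treatment(state: SimulationState, plan: TreatmentPlan) -> SimulationState:
    """Overwrite live parameters and/or restore oligodendrocyte blocks."""
    if plan.new_b_R is not None:
        state.b_R = plan.new_b_R
    if plan.new_omega is not None:
        state.omega = plan.new_omega
    if plan.new_lambda is not None:
        state.lambda_ = plan.new_lambda
    if plan.new_omega is not None and plan.reevaluate_nonmyelinating:
        # under the raised tolerance, stressed-but-alive cells resume repair
        sigma = my.compute_sigma(state.myelin, state.oligos)
        unlatch = (state.oligos.status == my.NONMYELINATING) & (sigma < state.omega)
        state.oligos.status[unlatch] = my.MYELINATING
    f = plan.restore_fraction
    if f is not None and f > 0:
        grid, field = state.oligos, state.myelin
        pick = state.rng.random(grid.status.shape) < f
        if not plan.restore_all_blocks:
            pick &= grid.status != my.MYELINATING
        if pick.any():
            grid.status[pick] = my.MYELINATING
            b = grid.block
            sites = np.repeat(np.repeat(pick, b, axis=0), b, axis=1)
            field.state[sites] = field.n_states
            field.repair_counter[sites] = 0
            # cells standing on restored myelin are released from engagement
            pop = state.population
            if pop.engaged.any():
                par = np.nonzero(pop.engaged)[0]
                er = pop.reactivated[par, 1] - 1
                ec = pop.reactivated[par, 0] - field.col_offset
                pop.engaged[par[sites[er, ec]]] = False
    return state


def scenario_library(intervention_day: float = 80.0) -> dict[str, Scenario]:
    """The named treatment scenarios compared throughout the analyses.

    Untreated baseline is b_R = 0.1, omega = 10, lambda = 14 with three
    relapses; all interventions commence at day 80 (after the first
    relapse) except the immediate DMT, which is a config variant with
    b_R = 0.025 for the whole run.
    """
    day = intervention_day
    resil = dict(new_omega=21, new_lambda=24)
    combined = dict(new_b_R=0.025, restore_fraction=1.0, **resil)
    lib = {
        "untreated": Scenario("untreated", {}, None),
        "immediate-dmt": Scenario("immediate-dmt", {"b_R": 0.025}, None),
        "delayed-dmt": Scenario(
            "delayed-dmt", {}, TreatmentPlan(day, new_b_R=0.025)),
        "restore-only": Scenario(
            "restore-only", {}, TreatmentPlan(day, restore_fraction=1.0)),
        "resilience-only": Scenario(
            "resilience-only", {}, TreatmentPlan(day, **resil)),
        "restore-resilience": Scenario(
            "restore-resilience", {},
            TreatmentPlan(day, restore_fraction=1.0, **resil)),
        "combined": Scenario("combined", {}, TreatmentPlan(day, **combined)),
    }
    for f in (0.75, 0.5, 0.25):
        name = f"combined-{int(f * 100)}"
        lib[name] = Scenario(
            name, {}, TreatmentPlan(day, new_b_R=0.025, restore_fraction=f,
                                    new_omega=21, new_lambda=24))
    return lib
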