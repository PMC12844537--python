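"""Myelin damage/repair state machine and oligodendrocyte stress responses.

Each parenchyma lattice site carries one myelin agent with an integer state
in [1, S]: S is fully intact, 1 fully degraded, intermediate values partial
damage.  Each oligodendrocyte owns a 5x5 block of sites.  Its stress sigma
is the count of fully degraded (state 1) sites in the block; crossing the
remyelination threshold omega halts repair in the block (integrated stress
response), crossing the apoptosis threshold lambda kills the cell and zeroes
all 25 sites.  Both transitions are one-way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import BlockDivisibilityError, SimulationConfig

__all__ = [
    "MyelinField",
    "OligoGrid",
    "MYELINATING",
    "NONMYELINATING",
    "APOPTOTIC",
    "init_fields",
    "degrade",
    "repair",
    "compute_sigma",
    "update_oligo_status",
    "myelin_metrics",
    "write_snapshot",
]

MYELINATING = 0
NONMYELINATING = 1
APOPTOTIC = 2

_STATUS_NAMES = {MYELINATING: "myelinating", NONMYELINATING: "nonmyelinating",
                 APOPTOTIC: "apoptotic"}


@dataclass
class MyelinField:
    """Per-site myelin states and repair counters over the parenchyma.

    Arrays are indexed ``[row - 1, col - col_offset]`` where ``col_offset``
    is the 1-based lattice column of the leftmost parenchyma column.
    """

    state: np.ndarray          # int16 (height, parenchyma_width), values 1..S
    repair_counter: np.ndarray  # int16, steps of non-occupation accrued
    col_offset: int            # first parenchyma lattice column (default 9)
    n_states: int              # S

    def site_index(self, col: int, row: int) -> tuple[int, int]:
        """Array index of lattice site (col, row); raises if not parenchyma."""
        r, c = row - 1, col - self.col_offset
        h, w = self.state.shape
        if not (0 <= r < h and 0 <= c < w):
            raise IndexError(f"({col}, {row}) is not a parenchyma site")
        return r, c


@dataclass
class OligoGrid:
    """Per-block oligodendrocyte status over the parenchyma.

    ``status`` is indexed ``[block_row, block_col]`` with the integer codes
    MYELINATING (0), NONMYELINATING (1), APOPTOTIC (2).  ``time_in_state``
    accumulates, per block, the number of steps spent in each status (used
    for behaviour-time summaries).
    """

    status: np.ndarray         # int8 (height/block, parenchyma_width/block)
    block: int                 # block side length (default 5)
    time_in_state: np.ndarray  # int64 (3, *status.shape)

    @property
    def n_blocks(self) -> int:
        return self.status.size

    def block_of_site(self, field: MyelinField, col: int, row: int) -> tuple[int, int]:
        r, c = field.site_index(col, row)
        return r // self.block, c // self.block

    def status_name(self, br: int, bc: int) -> str:
        return _STATUS_NAMES[int(self.status[br, bc])]


def init_fields(config: SimulationConfig) -> tuple[MyelinField, OligoGrid]:
    """Fully intact myelin and a uniform grid of myelinating oligodendrocytes.

    At the default geometry this creates 30,000 myelin sites and
    60 x 20 = 1200 oligodendrocyte blocks.
    """
    h, w, b = config.lattice_height, config.parenchyma_width, config.oligo_block
    if w % b or h % b:
        raise BlockDivisibilityError(
            f"parenchyma {w}x{h} not divisible into {b}x{b} blocks")
    field = MyelinField(
        state=np.full((h, w), config.n_myelin_states, dtype=np.int16),
        repair_counter=np.zeros((h, w), dtype=np.int16),
        col_offset=config.blood_width + config.pvs_width + 1,
        n_states=config.n_myelin_states,
    )
    grid = OligoGrid(
        status=np.zeros((h // b, w // b), dtype=np.int8),
        block=b,
        time_in_state=np.zeros((3, h // b, w // b), dtype=np.int64),
    )
    return field, grid


def _occupancy_mask(field: MyelinField, occupied_sites) -> np.ndarray:
    """Boolean (height, width) mask from an iterable of (col, row) pairs."""
    occ = np.zeros(field.state.shape, dtype=bool)
    for col, row in occupied_sites:
        occ[field.site_index(col, row)] = True
    return occ


def degrade(field: MyelinField, occupied_sites, per_agent: bool = False) -> int:
    """Degrade myelin under reactivated T-cell occupation; return #decrements.

    ``occupied_sites`` holds the (col, row) lattice sites occupied by at
    least one engaged reactivated T cell this step.  Each such site with
    state > 1 loses exactly one state regardless of how many cells occupy it
    (set ``per_agent=True`` to decrement once per occupant instead).  Repair
    counters of occupied sites are reset.
    """
    if per_agent:
        n = 0
        for col, row in occupied_sites:
            idx = field.site_index(col, row)
            if field.state[idx] > 1:
                field.state[idx] -= 1
                n += 1
            field.repair_counter[idx] = 0
        return n
    occ = _occupancy_mask(field, occupied_sites)
    hit = occ & (field.state > 1)
    field.state[hit] -= 1
    field.repair_counter[occ] = 0
    return int(hit.sum())


def repair(field: MyelinField, grid: OligoGrid, occupied_sites,
           config: SimulationConfig) -> int:
    """Advance repair counters and remyelinate; return #state increments.

    A damaged site (state < S) accrues one counter tick per step in which it
    is unoccupied by reactivated T cells and its block is still myelinating;
    on reaching ``repair_delay`` (W) the site gains one state and the counter
    resets.  Occupation or a non-myelinating block resets the counter to 0.
    """
    occ = _occupancy_mask(field, occupied_sites)
    return repair_masked(field, grid, occ, config.repair_delay)


def repair_masked(field: MyelinField, grid: OligoGrid, occ: np.ndarray,
                  delay: int) -> int:
    """Vectorised repair given a boolean occupancy mask (engine fast path)."""
    b = grid.block
    block_ok = grid.status == MYELINATING
    site_ok = np.repeat(np.repeat(block_ok, b, axis=0), b, axis=1)
    field.repair_counter[occ | ~site_ok] = 0
    eligible = site_ok & ~occ & (field.state < field.n_states)
    field.repair_counter[eligible] += 1
    done = eligible & (field.repair_counter >= delay)
    field.state[done] += 1
    field.repair_counter[done] = 0
    return int(done.sum())


def compute_sigma(field: MyelinField, grid: OligoGrid) -> np.ndarray:
    """Per-block stress: the count of fully degraded (state 1) sites."""
    b = grid.block
    h, w = field.state.shape
    damaged = field.state == 1
    return damaged.reshape(h // b, b, w // b, b).sum(axis=(1, 3))


def update_oligo_status(grid: OligoGrid, sigma: np.ndarray,
                        config_or_omega, lambda_: int | None = None,
                        field: MyelinField | None = None) -> OligoGrid:
    """Apply threshold crossings; transitions are one-way.

    Myelinating blocks with sigma >= omega stop myelinating; blocks no
    longer myelinating with sigma >= lambda undergo apoptosis, which sets
    every site in the block to state 1 permanently (both transitions can
    fire in the same step when sigma jumps past both thresholds).
    """
    if lambda_ is None:
        omega, lam = config_or_omega.omega, config_or_omega.lambda_
    else:
        omega, lam = config_or_omega, lambda_
    st = grid.status
    st[(st == MYELINATING) & (sigma >= omega)] = NONMYELINATING
    newly_apoptotic = (st == NONMYELINATING) & (sigma >= lam)
    st[newly_apoptotic] = APOPTOTIC
    if field is not None and newly_apoptotic.any():
        b = grid.block
        site_dead = np.repeat(np.repeat(newly_apoptotic, b, axis=0), b, axis=1)
        field.state[site_dead] = 1
        field.repair_counter[site_dead] = 0
    return grid


def myelin_metrics(field: MyelinField, grid: OligoGrid) -> dict:
    """Site-state and oligodendrocyte-status fractions (each triple sums to 1)."""
    s = field.state
    n = s.size
    intact = int((s == field.n_states).sum())
    damaged = int((s == 1).sum())
    nb = grid.n_blocks
    counts = np.bincount(grid.status.ravel(), minlength=3)
    return {
        "intact_fraction": intact / n,
        "partial_fraction": (n - intact - damaged) / n,
        "damaged_fraction": damaged / n,
        "myelinating_fraction": counts[MYELINATING] / nb,
        "nonmyelinating_fraction": counts[NONMYELINATING] / nb,
        "apoptotic_fraction": counts[APOPTOTIC] / nb,
    }


def write_snapshot(field: MyelinField, grid: OligoGrid, path) -> None:
    """Export the lattice as delimited integer grids (myelin then blocks)."""
    with open(path, "w") as fh:
        fh.write("# myelin states (rows x parenchyma columns), "
                 f"S={field.n_states}, first lattice column={field.col_offset}\n")
        np.savetxt(fh, field.state, fmt="%d")
        fh.write("# oligodendrocyte status (0=myelinating, 1=nonmyelinating, "
                 "2=apoptotic)\n")
        np.savetxt(fh, grid.status, fmt="%d")
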