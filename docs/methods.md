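# Model and methods

`mslesion` simulates the formation of a demyelinating lesion in a small
patch of central-nervous-system tissue as a stochastic, on-lattice
agent-based model, together with the treatment scenarios and sensitivity
analyses built on top of it.  This note records the model, its
parameters, the numerical choices, and what the implementation does and
does not claim.

## Domain

The tissue patch is a 2-D square lattice of 108 x 300 sites at
Δ = 10 µm spacing (the diameter of the immune cells modelled), split
into three vertical bands: peripheral blood (columns 1-3), perivascular
space (PVS, columns 4-8) and parenchyma (columns 9-108, a 1 x 3 mm
myelinated strip).  Columns and rows are 1-based in the public API, with
column 1 at the blood edge.  Rows wrap periodically (the vessel runs
vertically); the left edge reflects; the right edge absorbs (cells
wandering deeper into the parenchyma leave the model); PVMs are confined
to the PVS by reflecting interior boundaries.  Time advances in steps of
τ = 20 minutes, 72 steps per day; a standard run is 21,600 steps
(300 days).

## Agents

* **Primed T cells** spawn in the blood by independent per-site
  Bernoulli trials: probability ρ_R per site per step during a relapse
  and ρ_NR otherwise.  The defaults ρ_R = 0.0025 and ρ_NR = 0.0002
  reproduce mean influxes of 2.25 and 0.18 cells per step over the 900
  blood sites.  Relapses are scheduled windows (defaults: onsets at days
  0, 100, 200, each lasting 28 days, half-open).
* **The blood-brain barrier** sits between columns 3 and 4.  An eastward
  move across it succeeds with probability b_R (0.1 untreated), a
  westward move with b_L (0 by default: cells never return to the
  blood).  A failed crossing consumes the move.
* **Perivascular macrophages (PVMs)**: a fixed population of 45 cells
  (300 cells/mm² over the 0.15 mm² PVS) random-walking inside the PVS.
  When a primed T cell and a PVM occupy the same site the T cell is
  instantly replaced by a **reactivated T cell** at that site (antigen
  presentation); the PVM persists, and co-location is unlimited (no
  volume exclusion).
* **Reactivated T cells** random-walk with a chemotactic bias toward the
  nearest fully myelinated (intact) site once the first damage event has
  occurred anywhere (a global latch standing in for chemokine release).
  The bias magnitude is s_bias = β·exp(−k·D) with D the Euclidean
  distance to the nearest eligible site; the two directions toward the
  target gain s_bias split by component shares |Δx|/(|Δx|+|Δy|) and
  |Δy|/(|Δx|+|Δy|), the two opposite directions each lose s_bias/2.
  β = 0.5 keeps movement stochastic; β > 0.5 is supported by clamping
  negative probabilities to zero and renormalising (an explicit
  extension, off the default path).
* Primed and reactivated T cells die with probability ρ_d = 0.0049 per
  step, the 48-hour cytotoxic-T-cell half-life (0.35/day at 72
  steps/day).  PVMs neither die nor renew over the 300-day horizon.

## Myelin and oligodendrocytes

Each parenchyma site carries one myelin agent with an integer state in
[1, S]: S fully intact, 1 fully degraded.  A reactivated T cell entering
a site with state ≥ 2 becomes *engaged*: it stands still and the site
loses one state per step (one decrement per site per step regardless of
occupant count; a per-agent variant is available as a config toggle).
Engagement ends when the site reaches state 1.

Each oligodendrocyte owns a 5 x 5 block of sites (2,500 µm² of myelin
membrane; 1,200 cells over the parenchyma at 400 cells/mm²).  A damaged,
unoccupied site in a *myelinating* block accrues one repair tick per
step and regains one state after W ticks; occupation or loss of the
block's function resets the tick counter (the stricter reading of
"W steps of no occupation").  The block's stress σ is the count of its
fully degraded sites.  At σ ≥ ω the integrated stress response halts all
repair in the block (*non-myelinating*); at σ ≥ λ the cell undergoes
apoptosis and all 25 sites drop to state 1 permanently.  Both
transitions are one-way and may fire in the same step when σ jumps past
both thresholds.  Untreated thresholds are ω = 10, λ = 14.

## Step order and randomness

Each step applies, in a fixed order: spawn → synchronous movement
(primed, PVMs, unengaged reactivated cells) → antigen presentation →
degradation/engagement → repair → stress update (with apoptosis zeroing)
→ death → metrics.  The order is a modelling choice (conversions need
post-move co-location; the stress update follows damage so thresholds
fire at the earliest consistent moment) and is isolated in
`engine.advance`.  One seeded `numpy.random.Generator` drives a
replicate; the draw sequence is fixed by the step order and stable agent
iteration, so a (config, plan, seed) triple reproduces bit-identically.
Replicates derive child seeds from one base seed via `SeedSequence`.

### Numerical and tie-break conventions

* Nearest-myelin queries use the plain (non-wrapped) Euclidean metric;
  ties are broken deterministically by lowest row, then lowest column.
  By default the bias targets fully intact sites ("the nearest
  myelinated lattice site"); a `bias_target_intact=False` toggle widens
  eligibility to any site with remaining health (state ≥ 2), which is
  also the contract of the standalone `nearest_eligible_myelin`
  operation.  The choice matters: targeting intact myelin makes cells
  advance along the lesion front, whereas targeting any degradable site
  makes the cells already inside a block herd onto its residual sites
  and grind it to full damage — with herding, no repair speed can keep
  high stress tolerances (ω = 21, λ = 24) protective while damage at
  ω = 10 stays strong, and the treatment analyses become internally
  inconsistent.  With no eligible site anywhere (or an agent standing on
  its own target after a restoration) movement falls back to the
  unbiased walk.
* When the bias target is axis-aligned, the favoured direction of the
  zero component keeps the baseline 0.25 while the two opposing
  directions still lose s_bias/2; the favoured direction of a zero
  component is taken to be north/west.
* Degenerate inputs: `n_steps = 0` yields the initial-state metrics row
  only; an empty eligible set disables bias; configuration invariants
  (region widths, threshold ordering, block divisibility, probability
  ranges) are each enforced with a distinct error type.

The per-step hot path (parenchyma sweep, nearest-site search, movement
resolution) is compiled with numba; `mslesion.myelin` and
`mslesion.agents` keep plain-numpy reference implementations of every
operation and the test suite asserts the kernels match them exactly.

## Calibration of the unpublished parameters

S (myelin states), W (repair delay) and k (bias decay) have no printed
values in the main text and were calibrated once against the untreated
course: mean day-300 loss of intact myelin ≈ 96 % with a relapse-window
parenchyma population of reactivated T cells near the 30-40 cells/mm²
band.  The defaults are **S = 4, W = 16, k = 0.033 per lattice unit**.
With these, stripping a site takes S−1 = 3 steps (1 h) while a full
rebuild takes (S−1)·W = 48 steps (16 h), so repair is an order of
magnitude slower than damage — consistent with remyelination operating
on much longer timescales than T-cell attack — and the chemotactic pull
is short-ranged (decay length ~300 µm), so lesions grow from the PVS
outward by local recruitment rather than long-range homing.  This
combination reproduces, without further tuning, the graded response of
final myelin loss to barrier permeability that the treatment analyses
rest on; faster-repair/longer-range settings matched the untreated
course only while making low-permeability outcomes far too mild.

## Treatments

Treatments are step changes applied at the start of an intervention day
(default 80), with no pharmacokinetics:

* **DMT (BBB-targeted)**: b_R → 0.025, immediately (config variant) or
  at day 80.
* **Resilience (ISR-targeted)**: ω → 21, λ → 24.  On application,
  non-myelinating blocks whose σ sits below the new ω resume myelinating
  (re-evaluation under the raised tolerance); apoptosis stays absorbing.
  A `reevaluate_nonmyelinating=False` toggle keeps them latched instead.
* **Restoration (stem-cell/OPC)**: each block is selected independently
  with probability f and reset to myelinating with fully intact myelin;
  engaged T cells on restored sites are released.  Selection spans all
  blocks by default (restoring an intact block refreshes it); a toggle
  restricts restoration to stressed blocks.

## Experiments

`run_replicates` averages n seeded replicates with min/max envelopes.
The permeability sweep correlates, per window (each relapse span plus a
configurable 7 trailing days, and each remission gap), the maximum mean
reactivated count against the maximum mean lost-myelin percentage across
the swept b_R values (Pearson).  The threshold sweep covers the λ ≥ ω
triangle and summarises each behaviour's trapezoidal time integral
normalised by the horizon, i.e. its time share in [0, 1].  Behaviour
time per oligodendrocyte is accumulated exactly during the run (steps
spent in each status), so the swarm table is available for any scenario
including restorations.  The treatment comparison reports the final-day
myelinating fraction for the ten canonical scenarios.

## Scales used by the shipped checks

The acceptance script runs every scenario group at the paper's full
scale (108 x 300 lattice, 300 days) with 10 replicates per group — the
package's chosen desk scale for a single-CPU recomputation (a replicate
takes ~10-15 s).  Unit and property tests run on a reduced 28 x 30
domain with raised rates, which exercises every mechanism (relapse
influx, conversion, lesion growth, threshold cascades, treatments)
within seconds.

## What the model does not capture

No B cells, memory cells or additional T-cell subsets; no explicit
chemokine field (the bias latch is a proxy); no spontaneous OPC
differentiation (oligodendrocytes are a closed population outside
restoration events); no vascular-network geometry or spatially varying
barrier permeability; no MRI/phenotype mapping.  The relapse schedule is
an explicit input, not a stochastic generator.  Results at day 300
should not be extrapolated further, since the omitted populations likely
matter to long-term dynamics.
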