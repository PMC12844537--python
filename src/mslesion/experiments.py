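"""Replicate-averaged experiments and sensitivity analyses.

Provides the replicate runner with min/max envelopes, the BBB-permeability
sweep with per-window correlations, the (omega, lambda) threshold sweep
with normalised area-under-curve summaries, per-oligodendrocyte
behaviour-time tables, and the treatment-comparison summary.

Replicates derive their seeds from one base seed via
``numpy.random.SeedSequence``, so every experiment is reproducible from
``(config, n, base_seed)`` alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .engine import _METRIC_COLUMNS, run_simulation
from .treatments import TreatmentPlan, scenario_library

__all__ = [
    "ReplicateSummary",
    "run_replicates",
    "sweep_bbb",
    "sweep_thresholds",
    "behaviour_time_swarm",
    "treatment_comparison",
]


@dataclass
class ReplicateSummary:
    """Per-step mean / min / max over n independent seeded replicates."""

    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    steps_per_day: int
    n: int
    base_seed: int
    columns: tuple = _METRIC_COLUMNS
    block_time_in_state: list = dfield(default_factory=list)  # per replicate

    def series(self, name: str, which: str = "mean") -> np.ndarray:
        return getattr(self, which)[:, self.columns.index(name)]

    @property
    def day(self) -> np.ndarray:
        return np.arange(self.mean.shape[0]) / self.steps_per_day

    def at_day(self, name: str, day: float, which: str = "mean") -> float:
        i = min(int(round(day * self.steps_per_day)), self.mean.shape[0] - 1)
        return float(self.series(name, which)[i])


def replicate_seeds(base_seed: int, n: int) -> list:
    return np.random.SeedSequence(base_seed).spawn(n)


def run_replicates(config: SimulationConfig, plan: TreatmentPlan | None,
                   n: int, base_seed: int = 0) -> ReplicateSummary:
    """Average n independent replicates of one scenario.

    The envelope (``lo``/``hi``) holds the per-step extremes across
    replicates, matching how averaged disease courses are usually shaded.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    acc = lo = hi = None
    block_times = []
    for seed in replicate_seeds(base_seed, n):
        metrics, _ = run_simulation(config, plan=plan, seed=seed)
        d = metrics.data
        if acc is None:
            acc, lo, hi = d.copy(), d.copy(), d.copy()
        else:
            acc += d
            np.minimum(lo, d, out=lo)
            np.maximum(hi, d, out=hi)
        block_times.append(metrics.block_time_in_state)
    return ReplicateSummary(mean=acc / n, lo=lo, hi=hi,
                            steps_per_day=config.steps_per_day, n=n,
                            base_seed=base_seed, block_time_in_state=block_times)


@dataclass
class SweepResult:
    """Axis values with per-cell replicate-averaged summaries."""

    axis: list
    summaries: dict           # axis value -> ReplicateSummary
    n: int
    correlations: pd.DataFrame | None = None


def _correlation_windows(config: SimulationConfig, trailing_days: float):
    """(kind, day_start, day_stop) windows: each relapse span plus its
    trailing days, and the remission gaps between relapse spans."""
    windows = []
    onsets = sorted(config.relapse_onsets)
    horizon = config.n_days
    for i, onset in enumerate(onsets):
        stop = onset + config.relapse_duration_days
        windows.append(("relapse", onset, min(stop + trailing_days, horizon)))
        nxt = onsets[i + 1] if i + 1 < len(onsets) else horizon
        if stop < nxt:
            windows.append(("remission", stop, min(nxt, horizon)))
    return [(kind, d0, d1) for kind, d0, d1 in windows
            if d0 < horizon and d1 > d0]


def sweep_bbb(values, config: SimulationConfig, n: int = 20,
              base_seed: int = 0, trailing_days: float = 7.0) -> SweepResult:
    """Sweep the BBB permeability ``b_R`` and correlate cells with damage.

    For every window (each relapse span plus ``trailing_days``, and each
    remission gap) the Pearson correlation across the swept ``b_R`` values
    is computed between the window's maximum mean reactivated T-cell count
    and its maximum mean lost-myelin percentage.
    """
    values = list(values)
    summaries = {v: run_replicates(config.replace(b_R=v), None, n, base_seed)
                 for v in values}
    rows = []
    spd = config.steps_per_day
    for kind, d0, d1 in _correlation_windows(config, trailing_days):
        i0, i1 = int(round(d0 * spd)), int(round(d1 * spd)) + 1
        max_react, max_lost = [], []
        for v in values:
            s = summaries[v]
            max_react.append(s.series("reactivated")[i0:i1].max())
            max_lost.append(100.0 * (1.0 - s.series("intact_fraction")[i0:i1]).max())
        if len(values) < 2:
            warnings.warn("correlation undefined for a single-value sweep")
            r = np.nan
        else:
            r = float(np.corrcoef(max_react, max_lost)[0, 1])
        rows.append({"window": kind, "day_start": d0, "day_stop": d1,
                     "max_reactivated_range": (min(max_react), max(max_react)),
                     "pearson_r": r})
    return SweepResult(axis=values, summaries=summaries, n=n,
                       correlations=pd.DataFrame(rows))


def sweep_thresholds(config: SimulationConfig, n: int = 20,
                     omegas=None, lambdas=None, base_seed: int = 0
                     ) -> pd.DataFrame:
    """Sweep the (omega, lambda) triangle and summarise behaviour AUCs.

    For each admissible pair (lambda >= omega) the time integral of each
    oligodendrocyte-behaviour fraction is computed by the trapezoidal rule
    over steps and normalised by the horizon, so each AUC is the behaviour's
    time share in [0, 1] and the three AUCs sum to one.
    """
    block_area = config.oligo_block**2
    omegas = list(omegas) if omegas is not None else list(range(1, block_area + 1))
    lambdas = list(lambdas) if lambdas is not None else list(range(1, block_area + 1))
    rows = []
    for om in omegas:
        for lam in lambdas:
            if lam < om:
                continue
            cfg = config.replace(omega=om, lambda_=lam)
            s = run_replicates(cfg, None, n, base_seed)
            row = {"omega": om, "lambda": lam}
            for name in ("myelinating", "nonmyelinating", "apoptotic"):
                frac = s.series(f"{name}_fraction")
                row[f"auc_{name}"] = float(
                    np.trapezoid(frac, dx=1.0) / (len(frac) - 1))
            rows.append(row)
    return pd.DataFrame(rows)


def behaviour_time_swarm(summary: ReplicateSummary) -> pd.DataFrame:
    """Days spent by every oligodendrocyte in each behaviour, per replicate.

    Long-format table with columns (replicate, block, behaviour, days); the
    three behaviour times of any block sum to the simulated horizon.
    """
    names = ("myelinating", "nonmyelinating", "apoptotic")
    rows = []
    for rep, times in enumerate(summary.block_time_in_state):
        days = times.reshape(3, -1) / summary.steps_per_day
        for s, name in enumerate(names):
            rows.append(pd.DataFrame({
                "replicate": rep,
                "block": np.arange(days.shape[1]),
                "behaviour": name,
                "days": days[s],
            }))
    return pd.concat(rows, ignore_index=True)


def treatment_comparison(n: int = 40, config: SimulationConfig | None = None,
                         base_seed: int = 0, scenarios=None) -> pd.DataFrame:
    """Day-300 myelinating-oligodendrocyte fractions across the scenario set.

    One row per scenario with the replicate mean and min/max envelope of
    the final-step myelinating fraction (plus the intact-myelin fraction
    for context), in the canonical comparison order: untreated, delayed
    DMT, immediate DMT, restoration, resilience, both, and the combined
    DMT + oligodendrocyte therapy at 100/75/50/25 % re-establishment.
    """
    config = config or SimulationConfig()
    lib = scenario_library()
    order = scenarios or ["untreated", "delayed-dmt", "immediate-dmt",
                          "restore-only", "resilience-only", "restore-resilience",
                          "combined", "combined-75", "combined-50", "combined-25"]
    rows = []
    for name in order:
        sc = lib[name] if isinstance(name, str) else name
        cfg = sc.configure(config)
        s = run_replicates(cfg, sc.plan, n, base_seed)
        rows.append({
            "scenario": sc.name,
            "myelinating_mean": s.mean[-1, s.columns.index("myelinating_fraction")],
            "myelinating_min": s.lo[-1, s.columns.index("myelinating_fraction")],
            "myelinating_max": s.hi[-1, s.columns.index("myelinating_fraction")],
            "intact_myelin_mean": s.mean[-1, s.columns.index("intact_fraction")],
        })
    return pd.DataFrame(rows)
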