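"""Figure rendering for sweep and comparison outputs.

Matplotlib is imported lazily so the simulation core has no plotting
dependency; every function writes a raster image and returns its path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_bbb_heatmaps(result, path) -> Path:
    """Reactivated counts and lost-myelin % as (b_R x time) heatmaps."""
    plt = _mpl()
    values = result.axis
    day = result.summaries[values[0]].day
    react = np.array([result.summaries[v].series("reactivated") for v in values])
    lost = np.array([100 * (1 - result.summaries[v].series("intact_fraction"))
                     for v in values])
    fig, axes = plt.subplots(1, 2, figsize=(10, 3.2), constrained_layout=True)
    for ax, data, title in [(axes[0], react, "reactivated T cells"),
                            (axes[1], lost, "lost myelin (%)")]:
        im = ax.pcolormesh(day, values, data, shading="nearest")
        ax.set_xlabel("day")
        ax.set_ylabel("$b_R$")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_threshold_heatmaps(df, path) -> Path:
    """Normalised behaviour AUCs over the (omega, lambda) triangle."""
    plt = _mpl()
    oms = sorted(df["omega"].unique())
    lams = sorted(df["lambda"].unique())
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6), constrained_layout=True)
    for ax, name in zip(axes, ("myelinating", "nonmyelinating", "apoptotic")):
        grid = np.full((len(lams), len(oms)), np.nan)
        for _, row in df.iterrows():
            grid[lams.index(row["lambda"]), oms.index(row["omega"])] = (
                row[f"auc_{name}"])
        im = ax.pcolormesh(oms, lams, grid, shading="nearest",
                           vmin=0, vmax=1)
        ax.set_xlabel(r"$\omega$")
        ax.set_ylabel(r"$\lambda$")
        ax.set_title(f"{name} time share")
        fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_behaviour_swarm(df, path, rng_seed: int = 0) -> Path:
    """Jittered per-oligodendrocyte days spent in each behaviour."""
    plt = _mpl()
    rng = np.random.default_rng(rng_seed)
    names = ("myelinating", "nonmyelinating", "apoptotic")
    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    for i, name in enumerate(names):
        days = df.loc[df["behaviour"] == name, "days"].to_numpy()
        ax.plot(i + rng.uniform(-0.25, 0.25, days.size), days, ".",
                markersize=2, alpha=0.4)
    ax.set_xticks(range(3), names)
    ax.set_ylabel("days in behaviour")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_treatment_comparison(df, path) -> Path:
    """Final-day myelinating fraction per scenario with min/max whiskers."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(8, 4), constrained_layout=True)
    x = np.arange(len(df))
    err = np.vstack([df["myelinating_mean"] - df["myelinating_min"],
                     df["myelinating_max"] - df["myelinating_mean"]])
    ax.bar(x, df["myelinating_mean"], yerr=err, capsize=3)
    ax.set_xticks(x, df["scenario"], rotation=45, ha="right")
    ax.set_ylabel("myelinating fraction, final day")
    ax.set_ylim(0, 1.05)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
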