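"""Basic plots: cumulative/lag-specific RR curves and subgroup forest plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .effects import RRCurve


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_cumulative_rr(curve: RRCurve, path: str | Path, title: str = "") -> None:
    """Cumulative RR over temperature with its CI band; MaxRT-style layout."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.grid, curve.cumulative_rr, color="firebrick")
    ax.fill_between(curve.grid, curve.cumulative_lo, curve.cumulative_hi, alpha=0.25, color="firebrick")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.axvline(curve.reference, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("mean temperature (°C)")
    ax.set_ylabel("cumulative RR")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lag_rr(curve: RRCurve, temperature: float, path: str | Path, title: str = "") -> None:
    """Lag-specific RR at one temperature across lags 0..L."""
    plt = _plt()
    i = int(np.argmin(np.abs(curve.grid - temperature)))
    lags = np.arange(curve.lag_rr.shape[0])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        lags,
        curve.lag_rr[:, i],
        yerr=[curve.lag_rr[:, i] - curve.lag_lo[:, i], curve.lag_hi[:, i] - curve.lag_rr[:, i]],
        fmt="o",
        capsize=3,
    )
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel(f"RR at {curve.grid[i]:.1f} °C")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_forest(summary, path: str | Path, value: str = "rr_p99") -> None:
    """Forest-style display of per-subgroup RRs from a summary table."""
    plt = _plt()
    df = summary.reset_index(drop=True)
    labels = [f"{r.outcome}: {r.sex}/{r.age_band}" for r in df.itertuples()]
    y = np.arange(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    ax.errorbar(
        df[value],
        y,
        xerr=[df[value] - df[f"{value}_lo"], df[f"{value}_hi"] - df[value]],
        fmt="s",
        capsize=3,
        color="black",
    )
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("RR (P99 vs P50)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
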