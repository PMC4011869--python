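"""Report figures: growth curves per orientation group, angles, volume."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

GROUP_ORDER = ("AP", "SI", "AI", "ML")


def _cohort_series(measurements: pd.DataFrame, side: str) -> pd.DataFrame:
    """Cohort-mean value of each parameter per timepoint (chosen side)."""
    sub = measurements[measurements.side.isin([side, "B"])]
    return (
        sub.groupby(["group", "parameter", "timepoint"], sort=True)["value"]
        .mean()
        .reset_index()
    )


def _per_group_panels(df, transform, ylabel, title, filename):
    fig, axes = plt.subplots(2, 2, figsize=(10, 8), sharex=True)
    for ax, group in zip(axes.ravel(), GROUP_ORDER):
        gdf = df[df.group == group]
        for param, pdf in gdf.groupby("parameter"):
            pdf = pdf.sort_values("timepoint")
            t, v = pdf.timepoint.to_numpy(), pdf.value.to_numpy()
            t, v = transform(t, v)
            ax.plot(t, v, marker="o", ms=3, lw=1, label=param)
        ax.set_title(group)
        ax.set_xlabel("timepoint (month)")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=6, ncol=2)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(filename, dpi=110)
    plt.close(fig)


def plot_distances(measurements: pd.DataFrame, out_path, side: str = "L") -> None:
    df = _cohort_series(measurements[measurements.units == "cm"], side)
    _per_group_panels(
        df, lambda t, v: (t, v), "distance (cm)",
        "Inter-marker distances over the monitoring period", out_path,
    )


def plot_monthly_changes(measurements: pd.DataFrame, out_path, side: str = "L") -> None:
    df = _cohort_series(measurements[measurements.units == "cm"], side)
    _per_group_panels(
        df, lambda t, v: (t[1:], np.diff(v)), "monthly change (cm)",
        "Monthly changes of inter-marker distances", out_path,
    )


def plot_percent_changes(measurements: pd.DataFrame, out_path, side: str = "L") -> None:
    def pct(t, v):
        d = v[-1] - v[0]
        return t, 100.0 * (v - v[0]) / d if d != 0 else np.zeros_like(v)

    df = _cohort_series(measurements[measurements.units == "cm"], side)
    _per_group_panels(
        df, pct, "percent of total change (%)",
        "Percent of change of inter-marker distances", out_path,
    )


def _amount_change_percent(ax_row, t, v, label):
    ax_row[0].plot(t, v, marker="o", ms=3, label=label)
    ax_row[1].plot(t[1:], np.diff(v), marker="o", ms=3, label=label)
    d = v[-1] - v[0]
    p = 100.0 * (v - v[0]) / d if d != 0 else np.zeros_like(v)
    ax_row[2].plot(t, p, marker="o", ms=3, label=label)


def plot_angles(measurements: pd.DataFrame, out_path) -> None:
    ang = measurements[measurements.units == "deg"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for (param, side), sub in ang.groupby(["parameter", "side"]):
        if side == "mean":
            continue
        series = sub.groupby("timepoint")["value"].mean().sort_index()
        _amount_change_percent(
            axes, series.index.to_numpy(), series.to_numpy(), f"{param} ({side})"
        )
    for ax, ttl in zip(axes, ("angle (deg)", "monthly change (deg)", "percent of change (%)")):
        ax.set_xlabel("timepoint (month)")
        ax.set_ylabel(ttl)
        ax.legend(fontsize=7)
    fig.suptitle("Inter-segmental angles")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def plot_volume(measurements: pd.DataFrame, out_path) -> None:
    vol = measurements[measurements.parameter == "volume"]
    series = vol.groupby("timepoint")["value"].mean().sort_index()
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    _amount_change_percent(axes, series.index.to_numpy(), series.to_numpy(), "volume")
    for ax, ttl in zip(axes, ("volume (cm^3)", "monthly change (cm^3)", "percent of change (%)")):
        ax.set_xlabel("timepoint (month)")
        ax.set_ylabel(ttl)
    fig.suptitle("Mandibular bone volume")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
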