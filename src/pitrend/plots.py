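"""Plot artifacts: severity trajectories, prediction intervals, traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_prediction_report", "plot_trajectories", "export_traceplots"]


def plot_prediction_report(report: pd.DataFrame, ax=None):
    """Observed totals vs. sequential prediction intervals for one PI.

    ``report`` is one PI's slice of the prediction report (from-day,
    to-day, interval bounds, actual).  Points outside their interval are
    highlighted — the fail-safe signal for expert consultation.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.errorbar(report["to_day"], report["point"],
                yerr=[report["point"] - report["lower"],
                      report["upper"] - report["point"]],
                fmt="s", color="tab:blue", capsize=4,
                label="prediction interval")
    covered = report["covered"].astype(bool)
    ax.plot(report["to_day"][covered], report["actual"][covered], "o",
            color="tab:green", label="observed (inside)")
    if (~covered).any():
        ax.plot(report["to_day"][~covered], report["actual"][~covered], "X",
                color="tab:red", markersize=10, label="observed (outside)")
    ax.set_xlabel("day")
    ax.set_ylabel("total severity score")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_trajectories(records: pd.DataFrame, ax=None):
    """Total-score trajectories of every PI in a record table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    totals = records["total"] if "total" in records.columns else \
        records[["e", "s", "i", "g", "n", "p"]].sum(axis=1)
    frame = records.assign(_total=totals)
    for pid, grp in frame.groupby("pi_id"):
        grp = grp.sort_values("day")
        ax.plot(grp["day"], grp["_total"], marker="o", alpha=0.7, label=pid)
    ax.set_xlabel("day")
    ax.set_ylabel("total severity score")
    return ax


def export_traceplots(samples, outdir: str | Path,
                      parameters: list[str] | None = None) -> Path:
    """Write per-parameter trace plots (visual mixing check) to files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = samples._scalar_dataset(include_effects=False)
    names = parameters or list(data)
    for name in names:
        fig, ax = plt.subplots(figsize=(7, 2.5))
        for chain in data[name]:
            ax.plot(chain, lw=0.5, alpha=0.8)
        ax.set_title(name, fontsize=9)
        safe = name.replace("[", "_").replace("]", "").replace(",", "_")
        fig.savefig(outdir / f"trace_{safe}.png", dpi=100,
                    bbox_inches="tight")
        plt.close(fig)
    return outdir
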