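"""Matplotlib views of recall curves and replicate-overlap bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .analysis import OverlapReport, RecallReport

__all__ = ["plot_recall_curves", "plot_overlap_bars"]


def plot_recall_curves(report: RecallReport, ax=None):
    """One recall-vs-iteration curve per k."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for k, sub in report.frame.groupby("k"):
        ax.plot(sub.iteration, 100 * sub.recall, marker="o", label=f"top {k}")
    ax.set_xlabel("iteration")
    ax.set_ylabel("recall [%]")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax


def plot_overlap_bars(report: OverlapReport, k: int, ax=None):
    """Stacked bars: true top-k recalled by 3, 2 or 1 of three replicates."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = report.frame[report.frame.k == k]
    base = 0 * sub.by_3
    for col, color, label in [
        ("by_3", "black", "all three replicates"),
        ("by_2", "tab:orange", "two replicates"),
        ("by_1", "tab:gray", "one replicate"),
    ]:
        vals = 100 * sub[col] / k
        ax.bar(sub.iteration, vals, bottom=base, color=color, label=label)
        base = base + vals
    ax.set_xlabel("iteration")
    ax.set_ylabel(f"share of true top {k} [%]")
    ax.set_ylim(0, 100)
    ax.legend()
    return ax
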