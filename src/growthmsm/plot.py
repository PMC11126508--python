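"""Plotting helpers for traces and predicted-vs-observed prevalence."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .structure import STATE_NAMES

_COLORS = ("#7570b3", "#1b9e77", "#d95f02", "#e7298a")


def plot_trace(trace, ax=None, title=None):
    """State-occupancy curves over age for one Markov trace."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for s in range(4):
        ax.plot(trace.ages, trace.occupancy[:, s], label=STATE_NAMES[s],
                color=_COLORS[s])
    ax.set_xlabel("age (years)")
    ax.set_ylabel("proportion of cohort")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_cohort_panels(schedule, start_age=3.0, end_age=18.0):
    """Four panels: traces for cohorts starting 100% in each state."""
    from .trace import markov_trace

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True, sharey=True)
    for s, ax in enumerate(axes.ravel()):
        baseline = np.zeros(4)
        baseline[s] = 1.0
        tr = markov_trace(baseline, schedule, start_age, end_age)
        plot_trace(tr, ax=ax, title=f"baseline: {STATE_NAMES[s]}")
    fig.tight_layout()
    return fig


def plot_predicted_vs_observed(validation, ax=None):
    """Predicted (lines) and observed (points) prevalence per state by age.

    ``validation`` is the frame from
    :func:`growthmsm.trace.predicted_vs_observed`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for s, name in enumerate(STATE_NAMES):
        sub = validation[validation["state"] == name]
        ax.plot(sub["age"], sub["predicted"], color=_COLORS[s], label=name)
        ax.scatter(sub["age"], sub["observed"], color=_COLORS[s], s=18,
                   marker="o", facecolors="none")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("prevalence")
    ax.legend(fontsize=8)
    return ax
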