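"""Publication-style figures: step-count histograms and trace fits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .steps import StepFit
from .stoichiometry import STEP_CLASSES, ExpectedStepDistribution, StepHistogram

__all__ = ["plot_step_histogram", "plot_trace_fit"]

_DISPLAY = {"1": "1", "2": "2", "3": "3", "4": "4", "5": "5", ">5": ">", "x": "x"}


def plot_step_histogram(hist: StepHistogram,
                        expected: ExpectedStepDistribution | None = None,
                        ax: plt.Axes | None = None,
                        title: str | None = None) -> plt.Axes:
    """Bar chart of per-class frequencies with binomial error bars.

    Classes 1 and 2 are highlighted (single molecule vs the two-molecule
    signature); bar labels carry the raw counts and the axis title the
    colocalized fraction.  Optionally overlays the expected conditional
    distribution for a given true bound-molecule count, scaled to the
    classified spots.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.2))
    freqs = hist.frequencies
    errs = hist.error_bars
    xs = np.arange(len(STEP_CLASSES))
    colors = ["#3465a4", "#4e9a06"] + ["#888a85"] * 5
    ax.bar(xs, [freqs[c] for c in STEP_CLASSES],
           yerr=[errs[c] for c in STEP_CLASSES],
           color=colors, capsize=2)
    for x, c in zip(xs, STEP_CLASSES):
        if hist.counts[c]:
            ax.annotate(str(hist.counts[c]), (x, freqs[c] + errs[c]),
                        ha="center", va="bottom", fontsize=8)
    if expected is not None:
        scale = 100.0 * hist.n_classified / hist.total_rna_spots
        probs = np.zeros(6)
        for j in range(1, len(expected.conditional)):
            probs[min(j, 6) - 1] += expected.conditional[j]
        ax.plot(xs[:6], scale * probs, "k_", markersize=14,
                label=f"expected, k={expected.k}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xticks(xs, [_DISPLAY[c] for c in STEP_CLASSES])
    ax.set_xlabel("bleaching steps (n)")
    ax.set_ylabel("frequency (% of RNA spots)")
    ax.set_title(title or f"Coloc. spots {hist.colocalized_fraction:.0f}%",
                 fontsize=9)
    return ax


def plot_trace_fit(fit: StepFit, ax: plt.Axes | None = None) -> plt.Axes:
    """Intensity trace with its piecewise-constant segmentation overlaid."""
    if fit.trace is None:
        raise ValueError("fit carries no trace to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(5.0, 2.4))
    y = fit.trace.intensities
    t = np.arange(y.size) * fit.trace.exposure_ms / 1000.0
    ax.plot(t, y, color="#4e9a06", lw=0.7)
    bounds = [0] + [int(c) for c in fit.changepoints] + [y.size]
    for mean, a, b in zip(fit.segment_means, bounds[:-1], bounds[1:]):
        ax.plot(t[[a, b - 1]], [mean, mean], color="k", lw=1.6)
    label = fit.classification or f"{fit.n_down_steps} down"
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (a.u.)")
    ax.set_title(f"spot {fit.trace.spot_id}: {label}", fontsize=9)
    return ax
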