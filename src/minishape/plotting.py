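"""Minimal matplotlib views of profiles and differential distributions."""

from __future__ import annotations

import numpy as np

from .compare import DifferentialProfile, HISTOGRAM_BINS, OutlierReport
from .reactivity import ReactivityProfile


def plot_profiles(
    exp: ReactivityProfile,
    pred: ReactivityProfile | None = None,
    ax=None,
):
    """Overlay experimental (and optionally predicted) reactivity traces."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(1, len(exp) + 1)
    ax.plot(x[exp.mask], exp.finite_values(), color="seagreen", label="experimental")
    if pred is not None:
        ax.plot(
            x[pred.mask], pred.finite_values(), color="black", lw=1, label="predicted"
        )
    ax.set_xlabel("construct position")
    ax.set_ylabel("normalized reactivity")
    ax.legend(frameon=False)
    return ax


def plot_differential_histogram(
    deltas: DifferentialProfile, report: OutlierReport | None = None, ax=None
):
    """Histogram of differential reactivity (0.1-wide bins) with fences."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(deltas.finite_deltas(), bins=HISTOGRAM_BINS, color="0.6", edgecolor="w")
    if report is not None:
        for fence in (report.lower_fence, report.upper_fence):
            ax.axvline(fence, color="k", ls="--", lw=1)
    ax.set_xlabel("differential reactivity (experimental - predicted)")
    ax.set_ylabel("positions")
    return ax
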