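"""Diagnostic plots (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

import numpy as np


def plot_scan(windows, truth_segment_bp=None, ax=None):
    """BIC of every trial window against its left-breakpoint position.

    The zero line separates windows favoring the inversion model from those
    favoring the null; optionally shades the true inverted segment.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    x = np.array([w.left_bp.midpoint_bp for w in windows]) / 1e6
    y = np.array([w.bic for w in windows])
    ax.plot(x, y, ".", ms=3, color="steelblue")
    ax.axhline(0.0, color="black", lw=0.8)
    if truth_segment_bp is not None:
        ax.axvspan(truth_segment_bp[0] / 1e6, truth_segment_bp[1] / 1e6, alpha=0.15, color="orange")
    ax.set_xlabel("left breakpoint (Mb)")
    ax.set_ylabel("BIC")
    return ax
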