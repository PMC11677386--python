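"""Minimal agreement plots: scatter with identity line, Bland–Altman panel."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import bland_altman

__all__ = ["scatter_identity", "bland_altman_plot"]


def scatter_identity(reference, index, labels=("reference", "index"), ax=None):
    """Scatter of index vs reference with the identity line."""
    if ax is None:
        _, ax = plt.subplots()
    ref = np.asarray(reference, float)
    idx = np.asarray(index, float)
    ax.scatter(ref, idx, s=12, color="black")
    lo, hi = min(ref.min(), idx.min()), max(ref.max(), idx.max())
    ax.plot([lo, hi], [lo, hi], color="red", lw=1)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    return ax


def bland_altman_plot(reference, index, ax=None):
    """Differences (reference − index) vs pairwise means with bias and LoA lines."""
    if ax is None:
        _, ax = plt.subplots()
    ref = np.asarray(reference, float)
    idx = np.asarray(index, float)
    res = bland_altman(ref, idx)
    means = (ref + idx) / 2.0
    ax.scatter(means, ref - idx, s=12, color="black")
    ax.axhline(0.0, color="black", lw=1)
    ax.axhline(res.bias, color="black", ls="--", lw=1)
    for loa in (res.loa_low, res.loa_high):
        ax.axhline(loa, color="red", lw=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (reference - index)")
    return ax
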