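"""Thin matplotlib renderers over the exported tables and matrices."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_interactions_near_viewpoint(calls, vp, span_bp=500_000, ax=None):
    """Signal vs. distance on the cis chromosome, significant calls marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    cis = calls[calls["is_cis"] & calls["distance"].abs().le(span_bp)]
    ax.plot(cis["distance"], cis["signal"], color="0.6", lw=0.8)
    sig = cis[cis["significant"]]
    ax.scatter(sig["distance"], sig["signal"], c=-np.log10(sig["q"].clip(lower=1e-10)),
               cmap="Reds", s=12, zorder=3)
    ax.set_xlabel(f"distance to {vp.name} (bp)")
    ax.set_ylabel("normalized signal")
    return ax


def plot_overview_interactions(calls, ax=None):
    """Per-chromosome counts of significant interactions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    sig = calls[calls["significant"]]
    counts = sig.groupby("chrom").size()
    ax.bar(counts.index, counts.values, color="steelblue")
    ax.set_ylabel("significant interactions")
    return ax


def plot_domainogram(matrix, ax=None, cap=10.0):
    """Heat map of -log10(q) across window sizes and positions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t = matrix.transformed(cap)
    ax.imshow(
        t.to_numpy(), aspect="auto", origin="lower", cmap="viridis",
        extent=[t.columns.min(), t.columns.max(), t.index.min(), t.index.max()],
    )
    ax.set_xlabel(f"position on {matrix.viewpoint.chrom} (bp)")
    ax.set_ylabel("window size (bp)")
    return ax
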