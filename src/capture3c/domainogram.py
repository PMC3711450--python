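"""Domainogram construction: interaction significance across window sizes.

A single window size limits detection to interactions of roughly that size.
The domainogram re-runs the window-based analysis for every window size
from 2 to 30 kb (1-kb increments, 29 sizes) over a span around the
viewpoint and records the q-value of the window covering each genomic
position, producing a size-by-position significance matrix.  True
interactions appear as low-q columns that persist across many sizes.

For export the q-values are transformed to -log10(q) capped at 10, so that
larger is more significant and q = 0 does not overflow the color scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CallingConfig, fit_cis_background, pvalues_from_z, qvalues, zscores_cis
from .fragments import Viewpoint
from .normalize import fit_powerlaw, powerlaw_normalize, simple_rpm
from .counting import count_per_window

logger = logging.getLogger(__name__)

DEFAULT_SIZES = tuple(range(2_000, 31_000, 1_000))  # 29 window sizes


@dataclass
class DomainogramMatrix:
    """q-values per (window size, genomic position) around a viewpoint."""

    q: pd.DataFrame  # index: window size (bp); columns: position (bp)
    viewpoint: Viewpoint
    span_bp: int

    def transformed(self, cap: float = 10.0) -> pd.DataFrame:
        """-log10(q), capped, for color-scale plotting/export."""
        with np.errstate(divide="ignore"):
            t = -np.log10(self.q)
        return t.clip(upper=cap).fillna(0.0)

    def to_tsv(self, path, cap: float = 10.0) -> None:
        df = self.transformed(cap)
        df.index.name = "window_size"
        df.to_csv(path, sep="\t")


def domainogram_matrix(
    reads: pd.DataFrame,
    vp: Viewpoint,
    chrom_sizes: dict,
    span_bp: int = 500_000,
    sizes=DEFAULT_SIZES,
    config: CallingConfig | None = None,
    column_step: int = 1_000,
    min_count: int = 50,
) -> DomainogramMatrix:
    """Window-based interaction calling across a range of window sizes.

    For each size, non-overlapping windows are tiled over the whole cis
    chromosome, counted, normalized (power-law fit when enough windows pass
    the count filter, otherwise simple RPM) and scored against the spline
    background; the q of the window covering each ``column_step``-spaced
    position inside [viewpoint - span, viewpoint + span] is recorded.
    Tiling chromosome-wide keeps the normalization fit and the background
    model on the same footing as the ordinary window-based analysis; the
    span only selects which columns are reported.
    """
    config = config or CallingConfig()
    sizes = tuple(sizes)
    if span_bp < max(sizes):
        raise ValueError("span_bp must be at least the largest window size")
    chrom_len = chrom_sizes[vp.chrom]
    lo = max(0, int(vp.midpoint) - span_bp)
    hi = min(chrom_len, int(vp.midpoint) + span_bp)
    cis_reads = reads[reads["chrom"] == vp.chrom]
    positions = np.arange(lo, hi, column_step)
    mat = np.full((len(sizes), len(positions)), np.nan)
    for si, size in enumerate(sizes):
        windows = count_per_window(cis_reads, {vp.chrom: chrom_len}, size)
        windows = simple_rpm(windows)
        try:
            fit = fit_powerlaw(windows, viewpoint=vp, min_count=min_count)
            windows = powerlaw_normalize(windows, fit)
        except ValueError:
            windows["norm_rpm"] = windows["rpm"]
        bg = fit_cis_background(
            windows, vp, spar=config.spar,
            signed_distance=config.signed_distance,
        )
        z = zscores_cis(windows, bg)
        scored = ~np.isin(z.index.to_numpy(), bg.excluded_region_ids)
        z = z[scored]
        p = pvalues_from_z(z.to_numpy())
        q, _ = qvalues(p, fdr_level=config.fdr_level,
                       random_state=config.random_state)
        q_by_id = pd.Series(q, index=z.index)
        col_idx = np.minimum(positions // size, chrom_len // size)
        qcol = q_by_id.reindex(col_idx).to_numpy()
        mat[si] = qcol
    qdf = pd.DataFrame(mat, index=list(sizes), columns=positions)
    logger.info(
        "domainogram: %d sizes x %d positions around %s:%d",
        len(sizes), len(positions), vp.chrom, int(vp.midpoint),
    )
    return DomainogramMatrix(q=qdf, viewpoint=vp, span_bp=span_bp)
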