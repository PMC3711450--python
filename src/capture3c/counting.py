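"""Alignment loading and per-fragment / per-window read counting.

3C-seq reads start at the ligation junction, so a read is assigned to a
region by its strand-aware 5' position (alignment start on '+', alignment
end - 1 on '-'), not by midpoint or overlap.  The optional informative-read
filter keeps only reads whose 5' end abuts a restriction-fragment boundary,
as expected for genuine ligation products; reads from incompletely digested
or randomly sheared chromatin fail this test.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .fragments import FragmentMap

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "five_prime"]


def load_alignments(path: str | Path, min_mapq: int = 10) -> pd.DataFrame:
    """Load mapped reads from a BAM/SAM file into a read table.

    Unmapped, secondary and supplementary records are excluded, as are
    records with mapping quality below ``min_mapq`` (default 10, which
    discards typical multi-mappers).  Returns a DataFrame with columns
    chrom, start, end, strand, mapq, five_prime.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    rows = []
    try:
        with pysam.AlignmentFile(str(path), require_index=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                strand = "-" if rec.is_reverse else "+"
                start = rec.reference_start
                end = rec.reference_end
                five = start if strand == "+" else end - 1
                rows.append((rec.reference_name, start, end, strand,
                             rec.mapping_quality, five))
    except (OSError, ValueError) as exc:
        raise ValueError(f"could not read alignment file {path}: {exc}") from exc
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    logger.info("loaded %d reads from %s (min_mapq=%d)", len(reads), path, min_mapq)
    return reads


def _dedup(reads: pd.DataFrame) -> pd.DataFrame:
    return reads.drop_duplicates(subset=["chrom", "five_prime", "strand"])


def count_per_fragment(
    reads: pd.DataFrame,
    fm: FragmentMap,
    informative_only: bool = False,
    tolerance: int = 1,
    collapse_duplicates: bool = False,
) -> pd.DataFrame:
    """Count reads per restriction fragment by 5' position.

    Every fragment appears in the output with its raw_count (zeros included).
    With ``informative_only``, a read is kept only when its 5' position lies
    within ``tolerance`` bp of either fragment boundary (default 1 bp: the
    biochemically expected position is exactly at the boundary, but end
    repair and alignment clipping commonly shift one base).  Reads on
    chromosomes absent from the map are tallied as unassigned, available in
    ``result.attrs["unassigned"]``.
    """
    if collapse_duplicates:
        reads = _dedup(reads)
    out = fm.fragments[["chrom", "start", "end", "fragment_id"]].copy()
    out = out.rename(columns={"fragment_id": "region_id"})
    counts = np.zeros(len(out), dtype=np.int64)
    id_to_row = pd.Series(np.arange(len(out)), index=out["region_id"].to_numpy())
    unassigned = 0
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in fm.chromosomes:
            unassigned += len(sub)
            continue
        pos = sub["five_prime"].to_numpy()
        ids = fm.locate_positions(chrom, pos)
        off = ids < 0
        unassigned += int(off.sum())
        ids, pos = ids[~off], pos[~off]
        if informative_only and len(ids):
            frags = fm.fragments_on(chrom).set_index("fragment_id")
            starts = frags["start"].reindex(ids).to_numpy()
            ends = frags["end"].reindex(ids).to_numpy()
            keep = (pos - starts <= tolerance) | ((ends - 1) - pos <= tolerance)
            ids = ids[keep]
        if len(ids):
            rows = id_to_row.reindex(ids).to_numpy()
            counts += np.bincount(rows, minlength=len(out)).astype(np.int64)
    out["raw_count"] = counts
    out.attrs["unassigned"] = unassigned
    logger.info(
        "assigned %d reads to %d fragments (%d unassigned)",
        int(counts.sum()), len(out), unassigned,
    )
    return out


def read_chrom_sizes(source) -> dict[str, int]:
    """Chromosome sizes from a dict, a Series or a 2-column TSV path."""
    if isinstance(source, dict):
        return {str(k): int(v) for k, v in source.items()}
    if isinstance(source, pd.Series):
        return {str(k): int(v) for k, v in source.items()}
    df = pd.read_csv(source, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def count_per_window(
    reads: pd.DataFrame,
    chrom_sizes,
    window: int,
    overlapping: bool = False,
    collapse_duplicates: bool = False,
) -> pd.DataFrame:
    """Count reads per genomic window of size ``window``.

    Non-overlapping mode tiles each chromosome with half-open windows (last
    window truncated).  Overlapping mode uses step = window/2, so a read
    contributes to every (at most two) windows containing its 5' position.
    """
    sizes = read_chrom_sizes(chrom_sizes)
    if window < 1:
        raise ValueError("window must be positive")
    if window < 1000:
        logger.warning("window %d bp is below the recommended minimum of 1 kb", window)
    if window > max(sizes.values()):
        logger.warning(
            "window %d bp exceeds the longest chromosome; one truncated "
            "window per chromosome", window,
        )
    if collapse_duplicates:
        reads = _dedup(reads)
    step = window // 2 if overlapping else window
    rows = []
    region_id = 0
    per_chrom = {}
    for chrom, size in sizes.items():
        starts = np.arange(0, size, step, dtype=np.int64)
        ends = np.minimum(starts + window, size)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        ids = np.arange(region_id, region_id + len(starts))
        region_id += len(starts)
        per_chrom[chrom] = (starts, ends, ids)
        rows.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "region_id": ids}
        ))
    out = pd.concat(rows, ignore_index=True)
    counts = np.zeros(len(out), dtype=np.int64)
    offset = {c: int(v[2][0]) for c, v in per_chrom.items()}
    unassigned = 0
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in per_chrom:
            unassigned += len(sub)
            continue
        starts, ends, ids = per_chrom[chrom]
        pos = sub["five_prime"].to_numpy()
        inside = (pos >= 0) & (pos < sizes[chrom])
        unassigned += int((~inside).sum())
        pos = pos[inside]
        idx = pos // step
        idx = np.clip(idx, 0, len(starts) - 1)
        counts += np.bincount(idx + offset[chrom], minlength=len(out))
        if overlapping:
            prev = idx - 1
            ok = prev >= 0
            ok &= pos < starts[np.clip(prev, 0, None)] + window
            counts += np.bincount(prev[ok] + offset[chrom], minlength=len(out))
    out["raw_count"] = counts
    out.attrs["unassigned"] = unassigned
    return out
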