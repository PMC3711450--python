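"""Genome-browser and text export of signals and interaction calls.

bedGraph output follows the UCSC dialect: one ``track type=bedGraph`` header
line, then chrom/start/end/value records in 0-based half-open coordinates.
Zero-valued regions are omitted.  Text export writes one tab-delimited row
per region with floats at 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# fixed column order for call tables; extra columns are appended after these
CALL_COLUMNS = [
    "chrom", "start", "end", "region_id", "distance", "raw_count", "rpm",
    "norm_rpm", "signal", "z", "p", "q", "significant", "is_cis",
]


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def export_bedgraph(
    regions: pd.DataFrame,
    value_col: str,
    path: str | Path,
    track_name: str = "capture3c",
) -> Path:
    """Write one value per region as a bedGraph track.

    Regions are sorted by (chrom, start); overlapping regions cannot be
    represented in bedGraph and raise an error.  Zero values are omitted.
    """
    df = regions.sort_values(["chrom", "start"], kind="stable")
    for _, sub in df.groupby("chrom", sort=False):
        if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
            raise ValueError(
                "overlapping regions cannot be exported to bedGraph; "
                "use non-overlapping windows or fragments"
            )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track_name}\n")
        for _, row in df.iterrows():
            v = row[value_col]
            if v == 0 or (isinstance(v, float) and np.isnan(v)):
                continue
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{_fmt(v)}\n")
    logger.info("wrote bedGraph track %s to %s", track_name, path)
    return path


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Parse a bedGraph file back into a (chrom, start, end, value) table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def export_text(calls: pd.DataFrame, path: str | Path) -> Path:
    """Write a call (or signal) table as TSV with a fixed column order."""
    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    cols += [c for c in calls.columns if c not in cols]
    path = Path(path)
    out = calls[cols]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    logger.info("wrote %d rows to %s", len(out), path)
    return path


def read_calls(path: str | Path) -> pd.DataFrame:
    """Parse a TSV written by :func:`export_text`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("significant", "is_cis"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col] == "True"
    return df
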