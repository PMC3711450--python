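"""Gene annotation of significant interaction calls.

A gene is reported when any significant call overlaps its strand-aware
proximity window: [TSS - upstream, TES + downstream] in the gene's own
orientation (mirrored for minus-strand genes).  Defaults of 50 kb upstream
and 5 kb downstream capture promoter-proximal regulatory neighbourhoods.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class AnnotationConfig:
    upstream_bp: int = 50_000
    downstream_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("annotation distances must be >= 0")


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _genes_from_gtf(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "feature", "start", "end", "score",
               "strand", "frame", "attributes"],
        dtype={"chrom": str},
    )

    def name_of(attrs: str) -> str:
        d = dict(_GTF_ATTR.findall(attrs))
        return d.get("gene_name") or d.get("gene_id") or ""

    if (df["feature"] == "gene").any():
        genes = df[df["feature"] == "gene"].copy()
        genes["name"] = genes["attributes"].map(name_of)
    else:  # no explicit gene rows: take the span of each gene's features
        df["name"] = df["attributes"].map(name_of)
        genes = (
            df.groupby(["chrom", "strand", "name"], as_index=False)
            .agg(start=("start", "min"), end=("end", "max"))
        )
    genes["start"] = genes["start"].astype(int) - 1  # GTF is 1-based closed
    genes["end"] = genes["end"].astype(int)
    return genes[["chrom", "start", "end", "strand", "name"]].reset_index(drop=True)


def _genes_from_bed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 6:
        raise ValueError("BED gene models need >= 6 columns (strand required)")
    genes = df.iloc[:, [0, 1, 2, 5, 3]].copy()
    genes.columns = ["chrom", "start", "end", "strand", "name"]
    return genes.reset_index(drop=True)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Gene models from BED(12) or GTF; returns chrom/start/end/strand/name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene model file not found: {path}")
    if path.suffix.lower() in (".gtf", ".gff"):
        return _genes_from_gtf(path)
    return _genes_from_bed(path)


def annotate_genes(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Genes whose proximity window overlaps a significant call.

    Each gene is reported at most once, with its best (minimum q) supporting
    call and the number of overlapping significant calls.  Genes on
    chromosomes absent from the calls are silently unreported.
    """
    cfg = cfg or AnnotationConfig()
    sig = calls[calls["significant"]] if "significant" in calls.columns else calls
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "-":
            lo = g["start"] - cfg.downstream_bp
            hi = g["end"] + cfg.upstream_bp
        else:
            lo = g["start"] - cfg.upstream_bp
            hi = g["end"] + cfg.downstream_bp
        hits = sig[
            (sig["chrom"] == g["chrom"])
            & (sig["end"].to_numpy() > lo)
            & (sig["start"].to_numpy() < hi)
        ]
        if hits.empty:
            continue
        best = hits.loc[hits["q"].idxmin()]
        rows.append({
            "gene": g["name"], "chrom": g["chrom"],
            "gene_start": int(g["start"]), "gene_end": int(g["end"]),
            "strand": g["strand"],
            "window_start": int(max(lo, 0)), "window_end": int(hi),
            "n_calls": len(hits),
            "best_region_id": best["region_id"],
            "best_q": float(best["q"]), "best_z": float(best["z"]),
        })
    out = pd.DataFrame(
        rows,
        columns=["gene", "chrom", "gene_start", "gene_end", "strand",
                 "window_start", "window_end", "n_calls", "best_region_id",
                 "best_q", "best_z"],
    )
    return out.sort_values("best_q", kind="stable").reset_index(drop=True)
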