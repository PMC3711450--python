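"""Restriction fragment maps and viewpoint localization.

A 3C-seq/4C-seq library is anchored at one restriction fragment (the
viewpoint) and reads map to the fragments it was ligated to.  The native
resolution unit of the assay is therefore the restriction fragment: the
interval between consecutive recognition sites of the primary (typically
6-cutter) enzyme.  This module digests a genome in silico into an ordered,
gap-free fragment map and locates the viewpoint fragment within it.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import gzip
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes expanded to the concrete bases they stand for.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


@dataclass(frozen=True)
class Viewpoint:
    """The anchor fragment of the assay: chrom, [start, end) and a label."""

    chrom: str
    start: int
    end: int
    name: str = "viewpoint"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"viewpoint start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class FragmentMap:
    """Ordered, non-overlapping restriction fragments tiling each chromosome.

    ``fragments`` has columns chrom, start, end, fragment_id, with globally
    unique fragment ids increasing along the genome.
    """

    fragments: pd.DataFrame
    enzyme_site: str
    coordinates: str = "0-based half-open"
    _chrom_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._chrom_index = {
            chrom: sub.reset_index(drop=True)
            for chrom, sub in self.fragments.groupby("chrom", sort=False)
        }

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_index)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(sub["end"].iloc[-1]) for c, sub in self._chrom_index.items()}

    def __len__(self) -> int:
        return len(self.fragments)

    def fragments_on(self, chrom: str) -> pd.DataFrame:
        if chrom not in self._chrom_index:
            raise KeyError(f"chromosome {chrom!r} not in fragment map")
        return self._chrom_index[chrom]

    def locate_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Map positions to fragment ids; -1 for positions off the chromosome."""
        sub = self.fragments_on(chrom)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        ids = np.full(len(positions), -1, dtype=np.int64)
        ok = idx >= 0
        ok &= np.where(ok, positions < ends[np.clip(idx, 0, None)], False)
        ids[ok] = sub["fragment_id"].to_numpy()[idx[ok]]
        return ids

    def to_bed(self, path: str | Path) -> None:
        """Write the map as 4-column BED (chrom, start, end, fragment_id)."""
        self.fragments[["chrom", "start", "end", "fragment_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path: str | Path, enzyme_site: str = "") -> "FragmentMap":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "fragment_id"],
        )
        return cls(df, enzyme_site)


def reverse_complement(site: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(site.upper()))


def _site_pattern(site: str) -> re.Pattern:
    # Expand IUPAC codes in the site to character classes; ambiguous letters in
    # the genome itself never match (strict A/C/G/T classes, conservative).
    parts = []
    for b in site.upper():
        bases = IUPAC_CODES[b]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so that overlapping occurrences are all found
    return re.compile(f"(?=({''.join(parts)}))")


def read_genome(source) -> dict[str, str]:
    """Return {name: sequence} from a FASTA path (gzip allowed) or a mapping."""
    if isinstance(source, dict):
        return {str(k): str(v).upper() for k, v in source.items()}
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def digest_genome(
    genome,
    recognition_site: str,
    cut_offset: int = 0,
) -> FragmentMap:
    """Digest a genome at every occurrence of ``recognition_site``.

    Cut positions default to the start coordinate of each exact forward-strand
    occurrence of the site (the site belongs to the downstream fragment);
    ``cut_offset`` shifts cuts by the enzyme's cleavage offset if desired.
    Fragments are the half-open intervals between consecutive cuts plus the
    chromosome ends; zero-length fragments are dropped.  Palindromic sites are
    searched on the forward strand only; a non-palindromic site triggers a
    warning and a both-strand search.
    """
    genome = read_genome(genome)
    if not genome:
        raise ValueError("empty genome")
    site = recognition_site.upper()
    if len(site) < 4:
        raise ValueError(f"recognition site too short: {site!r} (need >= 4 bp)")
    bad = set(site) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"non-IUPAC characters in recognition site: {sorted(bad)}")

    patterns = [_site_pattern(site)]
    rc = reverse_complement(site)
    if rc != site:
        warnings.warn(
            f"recognition site {site} is not palindromic; searching both strands"
        )
        patterns.append(_site_pattern(rc))

    rows = []
    next_id = 0
    for chrom, seq in genome.items():
        length = len(seq)
        if length == 0:
            raise ValueError(f"empty sequence for chromosome {chrom!r}")
        if not set(seq) <= set(IUPAC_CODES):
            bad = sorted(set(seq) - set(IUPAC_CODES))
            raise ValueError(f"non-IUPAC characters in {chrom!r}: {bad}")
        cuts = {0, length}
        for pat in patterns:
            for m in pat.finditer(seq):
                pos = m.start() + cut_offset
                if 0 <= pos <= length:
                    cuts.add(pos)
        bounds = sorted(cuts)
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e > s:  # zero-length fragments dropped
                rows.append((chrom, s, e, next_id))
                next_id += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id"])
    logger.info(
        "digested %d chromosome(s) with %s into %d fragments",
        len(genome), site, len(df),
    )
    return FragmentMap(df, site)


def locate_viewpoint_fragment(vp: Viewpoint, fm: FragmentMap) -> int:
    """Fragment id with maximal overlap with the viewpoint; ties -> lower start."""
    if vp.chrom not in fm.chromosomes:
        raise KeyError(f"viewpoint chromosome {vp.chrom!r} not in fragment map")
    sub = fm.fragments_on(vp.chrom)
    overlap = np.minimum(sub["end"].to_numpy(), vp.end) - np.maximum(
        sub["start"].to_numpy(), vp.start
    )
    best = int(np.argmax(overlap))  # argmax takes the first (lowest start) on ties
    if overlap[best] <= 0:
        raise ValueError(f"viewpoint {vp.name!r} overlaps no fragment")
    return int(sub["fragment_id"].iloc[best])
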