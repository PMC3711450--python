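"""Synthetic genomes and 3C-seq alignments with known ground truth.

The generator emulates the structure the calling model assumes: contact
frequency on the viewpoint chromosome decays with distance as a shifted
power law w(d) = (1 + |d|/d0) ** -gamma (a power law rather than an
exponential, so that the count distribution entering the normalization fit
is itself power-law-like), selected fragments can be spiked by a fold
factor to act as true interactions, and a small fraction of reads lands
uniformly on trans chromosomes, mimicking random inter-chromosomal ligation.
Read 5' ends abut a fragment boundary with probability
``informative_fraction``, as real ligation-junction reads do.

Defaults: two 5-Mb chromosomes, HindIII (AAGCTT), gamma = 1.2, d0 = 10 kb,
trans_fraction = 0.05, informative_fraction = 0.9, 200,000 reads — small
enough that a full pipeline run takes seconds, large enough that per-
fragment counts carry the distance-decay signal the caller models.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .fragments import FragmentMap, Viewpoint, digest_genome, locate_viewpoint_fragment

logger = logging.getLogger(__name__)

DEFAULT_CHROM_LENGTHS = {"chr1": 5_000_000, "chr2": 5_000_000}


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic 3C-seq experiment."""

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    enzyme_site: str = "AAGCTT"
    viewpoint: Viewpoint | None = None  # default: fragment at chr1 midpoint
    n_reads: int = 200_000
    decay_exponent: float = 1.2
    d0: float = 10_000.0
    spikes: tuple = ()  # ((fragment_id, fold), ...)
    trans_fraction: float = 0.05
    informative_fraction: float = 0.9
    read_length: int = 36

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not 0 <= self.trans_fraction < 1:
            raise ValueError("trans_fraction must be in [0, 1)")
        if not 0 <= self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in [0, 1]")

    def resolve_viewpoint(self, fm: FragmentMap) -> Viewpoint:
        """The configured viewpoint, or the fragment at the first chromosome's midpoint."""
        if self.viewpoint is not None:
            return self.viewpoint
        chrom = next(iter(self.chrom_lengths))
        mid = self.chrom_lengths[chrom] // 2
        sub = fm.fragments_on(chrom)
        row = sub[(sub["start"] <= mid) & (sub["end"] > mid)].iloc[0]
        return Viewpoint(chrom, int(row["start"]), int(row["end"]), "sim-viewpoint")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.viewpoint is not None:
            d["viewpoint"] = dataclasses.asdict(self.viewpoint)
        d["spikes"] = [list(s) for s in self.spikes]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def choose_spike_fragments(
    fm: FragmentMap,
    vp: Viewpoint,
    n: int,
    rng: np.random.Generator,
    min_dist_bp: int = 100_000,
    max_dist_bp: int = 1_500_000,
    min_separation: int = 10,
) -> np.ndarray:
    """Pick n well-separated cis fragments to spike as true interactions.

    Candidates lie between ``min_dist_bp`` and ``max_dist_bp`` from the
    viewpoint (outside the steep near-viewpoint decay, but not at the far
    chromosome ends) and are kept at least ``min_separation`` fragments
    apart, so each spike represents a distinct interacting locus.
    """
    sub = fm.fragments_on(vp.chrom)
    mid = (sub["start"] + sub["end"]) / 2.0
    d = (mid - vp.midpoint).abs()
    cand = sub.index[(d >= min_dist_bp) & (d <= max_dist_bp)].to_numpy()
    rng.shuffle(cand)
    chosen: list[int] = []
    for i in cand:
        if all(abs(i - j) >= min_separation for j in chosen):
            chosen.append(int(i))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError(
            f"could only place {len(chosen)} of {n} spikes; widen the "
            "distance range or lower min_separation"
        )
    ids = sub["fragment_id"].to_numpy()[np.array(sorted(chosen))]
    return ids


def simulate_genome(cfg: SimulationConfig) -> dict[str, str]:
    """I.i.d. uniform A/C/G/T chromosomes, reproducible from the seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {}
    for chrom, length in cfg.chrom_lengths.items():
        idx = rng.integers(0, 4, size=int(length))
        genome[chrom] = bases[idx].tobytes().decode("ascii")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def ground_truth(cfg: SimulationConfig, fm: FragmentMap) -> pd.DataFrame:
    """Expected per-fragment read proportions and spike labels (seed-free)."""
    vp = cfg.resolve_viewpoint(fm)
    frags = fm.fragments.copy()
    mid = (frags["start"] + frags["end"]) / 2.0
    is_cis = (frags["chrom"] == vp.chrom).to_numpy()
    spikes = dict(cfg.spikes)
    bad = set(spikes) - set(frags.loc[is_cis, "fragment_id"])
    if bad:
        raise ValueError(
            f"spike fragment id(s) not on the viewpoint chromosome or absent "
            f"from the map: {sorted(bad)}"
        )
    weight = np.zeros(len(frags))
    d = np.abs(mid[is_cis] - vp.midpoint)
    weight[is_cis] = (1.0 + d / cfg.d0) ** (-cfg.decay_exponent)
    fold = frags["fragment_id"].map(spikes).fillna(1.0).to_numpy()
    weight *= fold
    n_trans = int((~is_cis).sum())
    prob = np.zeros(len(frags))
    prob[is_cis] = (1.0 - cfg.trans_fraction) * weight[is_cis] / weight[is_cis].sum()
    if n_trans:
        prob[~is_cis] = cfg.trans_fraction / n_trans
    else:
        prob[is_cis] /= prob[is_cis].sum()
    out = frags[["chrom", "start", "end", "fragment_id"]].copy()
    out["expected_proportion"] = prob
    out["spike_fold"] = fold
    out["is_cis"] = is_cis
    return out


def simulate_3cseq(
    cfg: SimulationConfig, fm: FragmentMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw reads from the generative model.

    Returns (reads, truth): a read table with the same columns that
    ``load_alignments`` produces (sorted by chromosome and position), and
    the per-fragment ground-truth table.  The truth table depends only on
    the configuration, not on the seed.
    """
    truth = ground_truth(cfg, fm)
    rng = np.random.default_rng([cfg.seed, 1])
    counts = rng.multinomial(cfg.n_reads, truth["expected_proportion"].to_numpy())
    frag_rows = np.repeat(np.arange(len(truth)), counts)
    starts = truth["start"].to_numpy()[frag_rows]
    ends = truth["end"].to_numpy()[frag_rows]
    chroms = truth["chrom"].to_numpy()[frag_rows]
    n = len(frag_rows)

    informative = rng.random(n) < cfg.informative_fraction
    at_end = rng.integers(0, 2, size=n).astype(bool)
    pos = np.where(at_end, ends - 1, starts)
    interior = starts + np.floor(
        rng.random(n) * (ends - starts)
    ).astype(np.int64)
    pos = np.where(informative, pos, interior)
    # informative reads point into the fragment; others get a random strand
    strand_minus = np.where(informative, at_end, rng.integers(0, 2, size=n).astype(bool))

    sizes = fm.chrom_sizes
    length = cfg.read_length
    aln_start = np.where(strand_minus, np.maximum(pos - length + 1, 0), pos)
    chrom_len = np.array([sizes[c] for c in chroms])
    aln_end = np.where(strand_minus, pos + 1, np.minimum(pos + length, chrom_len))

    reads = pd.DataFrame({
        "chrom": chroms,
        "start": aln_start,
        "end": aln_end,
        "strand": np.where(strand_minus, "-", "+"),
        "mapq": 60,
        "five_prime": pos,
    })
    reads = reads.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    logger.info("simulated %d reads (seed=%d)", len(reads), cfg.seed)
    return reads, truth


def write_alignments(
    reads: pd.DataFrame,
    chrom_sizes: dict[str, int],
    path: str | Path,
) -> Path:
    """Write a read table as coordinate-sorted BAM (indexed) or SAM."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_sizes)}
    sam = path.suffix == ".sam"
    mode = "w" if sam else "wb"
    ordered = reads.sort_values(["chrom", "start"], kind="stable")
    ordered = ordered.sort_values("start", kind="stable").sort_values(
        "chrom", key=lambda s: s.map(tid), kind="stable"
    )
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i, row in enumerate(ordered.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i:07d}"
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.mapq)
            a.flag = 16 if row.strand == "-" else 0
            span = int(row.end - row.start)
            a.cigarstring = f"{span}M"
            out.write(a)
    if not sam:
        pysam.index(str(path))
    logger.info("wrote %d alignments to %s", len(reads), path)
    return path


def simulate_dataset(
    cfg: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Full synthetic dataset on disk: FASTA, sorted BAM, truth TSV, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    fasta = write_fasta(genome, outdir / "genome.fa")
    fm = digest_genome(genome, cfg.enzyme_site)
    fm.to_bed(outdir / "fragments.bed")
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for c, n in fm.chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")
    reads, truth = simulate_3cseq(cfg, fm)
    bam = write_alignments(reads, fm.chrom_sizes, outdir / "reads.bam")
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    cfg.to_json(outdir / "config.json")
    return {
        "fasta": fasta, "bam": bam, "truth": truth_path,
        "fragments": outdir / "fragments.bed",
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "config": outdir / "config.json",
    }
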