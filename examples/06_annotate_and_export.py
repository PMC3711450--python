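"""Annotate significant calls with nearby genes and export browser tracks.

A gene is reported when a significant call falls inside its strand-aware
proximity window (50 kb upstream of the TSS to 5 kb downstream of the TES
by default).  Calls and signals are exported as bedGraph tracks for the
UCSC browser or IGV, and as tab-delimited tables.
"""

import dataclasses
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import capture3c as c3

warnings.filterwarnings("ignore")

cfg = c3.SimulationConfig(seed=8, n_reads=200_000)
genome = c3.simulate_genome(cfg)
fm = c3.digest_genome(genome, cfg.enzyme_site)
vp = cfg.resolve_viewpoint(fm)
spikes = c3.choose_spike_fragments(fm, vp, 5, np.random.default_rng(9))
cfg = dataclasses.replace(cfg, spikes=tuple((int(i), 10.0) for i in spikes))

reads, _ = c3.simulate_3cseq(cfg, fm)
counts = c3.count_per_fragment(reads, fm)
signals = c3.simple_rpm(counts)
signals = c3.powerlaw_normalize(signals, c3.fit_powerlaw(signals, viewpoint=vp))
calls = c3.call_interactions(signals, vp)

# put a toy gene next to each spiked fragment, plus one far away
frags = fm.fragments.set_index("fragment_id")
genes = pd.DataFrame({
    "chrom": [frags.loc[s, "chrom"] for s in spikes] + ["chr2"],
    "start": [frags.loc[s, "end"] + 20_000 for s in spikes] + [100_000],
    "end": [frags.loc[s, "end"] + 30_000 for s in spikes] + [110_000],
    "strand": ["+"] * len(spikes) + ["-"],
    "name": [f"gene{i}" for i in range(len(spikes))] + ["farGene"],
})
hits = c3.annotate_genes(calls, genes)
print(f"genes with a significant call in their proximity window: "
      f"{len(hits)} of {len(genes)}")
print(hits[["gene", "n_calls", "best_q"]].to_string(index=False))

with tempfile.TemporaryDirectory() as tmp:
    bg = c3.export_bedgraph(calls[calls["significant"]], "signal",
                            Path(tmp) / "calls.bedGraph",
                            track_name="interactions")
    tsv = c3.export_text(calls, Path(tmp) / "calls.tsv")
    print(f"\nbedGraph lines: {len(bg.read_text().splitlines())}")
    print("first track line:", bg.read_text().splitlines()[1])
    print(f"TSV rows: {len(tsv.read_text().splitlines()) - 1}")
# Each toy gene sits 20-30 kb from a spiked fragment, inside the 50-kb
# upstream window, so all spike-adjacent genes are reported; farGene is not.
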