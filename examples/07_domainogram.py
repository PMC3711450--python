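"""Domainogram: interaction significance across window sizes.

Re-runs the window-based analysis for every window size from 2 to 30 kb and
records the q-value of the window covering each position near the
viewpoint.  A true interaction shows up as a column of low q persisting
across many window sizes; single-size artifacts do not.
"""

import dataclasses
import warnings

import numpy as np

import capture3c as c3

warnings.filterwarnings("ignore")

cfg = c3.SimulationConfig(seed=10, n_reads=200_000)
genome = c3.simulate_genome(cfg)
fm = c3.digest_genome(genome, cfg.enzyme_site)
vp = cfg.resolve_viewpoint(fm)

# spike a ~10-kb block of adjacent fragments 250 kb from the viewpoint
sub = fm.fragments_on(vp.chrom)
d = (sub["start"] + sub["end"]) / 2 - vp.midpoint
block = sub[(d > 250_000) & (d < 262_000)]["fragment_id"]
cfg = dataclasses.replace(cfg, spikes=tuple((int(i), 10.0) for i in block))

reads, _ = c3.simulate_3cseq(cfg, fm)
mat = c3.domainogram_matrix(reads, vp, fm.chrom_sizes, span_bp=400_000)

t = mat.transformed()  # -log10(q), capped at 10
center = int(sub.set_index("fragment_id").loc[block[block.index[0]], "start"])
cols = mat.q.columns.to_numpy()
j = int(np.argmin(np.abs(cols - center - 5000)))
print(f"matrix: {mat.q.shape[0]} window sizes x {mat.q.shape[1]} positions")
print(f"spiked block at ~{center} "
      f"({(center - vp.midpoint) / 1000:+.0f} kb from the viewpoint)")
print(f"sizes with q <= 0.05 at the spiked column: "
      f"{int((mat.q.iloc[:, j] <= 0.05).sum())} of {mat.q.shape[0]}")
print(f"highest -log10(q) anywhere: {np.nanmax(t.to_numpy()):.1f}")
# Persistence across sizes distinguishes a real contact from window-size
# artifacts; the spiked block stays significant from 2 kb up to 30 kb.
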