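"""In-silico restriction digestion: genome -> fragment map.

Digests a simulated 2-Mb chromosome with HindIII (AAGCTT) and reports the
fragment-length distribution.  A 6-bp cutter hits a random sequence once
every 4^6 = 4096 bp on average, which sets the native resolution of a
viewpoint-capture experiment.
"""

import capture3c as c3

cfg = c3.SimulationConfig(seed=0, chrom_lengths={"chr1": 2_000_000})
genome = c3.simulate_genome(cfg)
fm = c3.digest_genome(genome, "AAGCTT")

lengths = fm.fragments["end"] - fm.fragments["start"]
print(f"fragments:        {len(fm)}")
print(f"mean length:      {lengths.mean():.0f} bp  (expected ~4096 bp)")
print(f"median length:    {lengths.median():.0f} bp")
print(f"longest fragment: {lengths.max()} bp")
# The mean tracks the 4^6 expectation; the median is shorter because
# fragment lengths are roughly exponential (many short, few long).
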