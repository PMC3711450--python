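# capture3c

Viewpoint-based interaction calling for 3C-seq / 4C-seq experiments: from
aligned reads to statistically scored, FDR-controlled chromatin interaction
calls, with replicate combination, gene annotation, genome-browser export
and a built-in ground-truth simulator.

## The problem

Chromosome conformation capture sequencing anchored at a single restriction
fragment (the *viewpoint*) measures which genomic regions are in physical
contact with that fragment — for example, which enhancers loop to a
promoter.  Two systematic effects dominate the raw read counts: sequencing
depth differs between libraries, and contact frequency decays with genomic
distance from the viewpoint simply because nearby sequences are tethered to
it during cross-linking.  `capture3c` corrects both and asks, per
restriction fragment or per window: *is the signal here higher than the
distance-decay background predicts?*

The package is for genomicists analyzing viewpoint-capture experiments and
for methods developers who need a fully simulatable pipeline with known
ground truth.

## The model

**Normalization.** Per-region read counts follow an approximate power law:
the reverse-cumulative distribution R(t) = #{regions with count ≥ t} is
close to linear in log–log space.  After removing regions with fewer than
50 reads and the viewpoint fragment ± 1, ordinary least squares on
log₁₀ R(t) vs log₁₀ t gives a slope and offset per library; counts are then
mapped onto a reference line with slope α = −1.35 and depth n₀ = 10⁶ reads,

&nbsp;&nbsp;&nbsp;&nbsp;t′ = 10^[(offset + slope·log₁₀ t − l_ref) / α],

yielding depth-independent "power-law RPM".  Simple RPM
(count / total × 10⁶) is also available.

**Cis calling.** On the viewpoint chromosome, a cubic smoothing spline
(smoothing parameter `spar`, default 0.1, range 0.06–0.4) of normalized
signal against distance to the viewpoint estimates the expected background
exp(d).  Each region is scored

&nbsp;&nbsp;&nbsp;&nbsp;z = (obs − exp) / SD,&nbsp;&nbsp;&nbsp;
SD = standard deviation of the residuals obs − exp,

converted to upper-tail normal p-values, then to q-values with a bootstrap
estimate of π₀ (the proportion of true nulls); regions with q ≤ 0.05 are
reported as interactions.

**Trans calling.** Regions on other chromosomes are scored with the same
z formula against the global mean and SD of the signal (regions within
±100 kb of the viewpoint excluded); no distance scaling is needed in trans.

**Replicates.** Each replicate is called separately; candidates significant
in ≥ 1 (union) or all (intersection) replicates are re-scored with Fisher's
combined probability test, X = −2 Σ ln pᵢ ~ χ²(2k), and fresh q-values.

## Worked example

`examples/04_call_interactions.py` simulates a default experiment — two
5-Mb chromosomes digested with HindIII, 200,000 reads decaying from a
mid-chromosome viewpoint, 5% trans background, three fragments spiked at
10× as true interactions — and runs the full pipeline:

```text
regions scored: 2498  (cis 1278, trans 1220)
significant at q <= 0.05: 3
spiked fragments recovered: 3 of 3

top calls (distance in bp from the viewpoint):
 region_id  distance  raw_count   signal    z         q
       732  3.24e+05       1588 1.28e+03 23.4 1.34e-119
       540 -4.28e+05       1140 1.01e+03 19.5   4.7e-83
       915  1.04e+06        455      523 8.97  8.33e-18
```

All three spiked fragments are recovered with large z (signal far above the
spline's expected decay at that distance) and no false positives among the
other ~2,500 regions.  The other scripts in `examples/` walk through
digestion, counting, normalization, replicate combination, gene annotation,
export and the domainogram, one capability each.

The same workflow is available from the shell:

```bash
capture3c simulate --seed 3 --n-spikes 10 --out sim/
capture3c pipeline --genome sim/genome.fa --bam sim/reads.bam \
    --viewpoint chr1:2496509-2504888 --enzyme-site AAGCTT --out results/
```

## Layout

- `src/capture3c/` — the library (`fragments`, `counting`, `normalize`,
  `smoothing`, `calling`, `replicates`, `annotate`, `export`,
  `domainogram`, `simulate`, `plotting`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — model, parameters, numerical choices, limitations
- `tests/` — pytest suite
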