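# tn5foot

Binding-site-resolution analysis of ATAC-Seq chromatin accessibility:
per-nucleotide Tn5 cut profiles, hexamer sequence-bias correction, and
transcription-factor footprint detection, together with the reporter-assay
and ATAC-qPCR normalization formulas used to relate accessibility to
enhancer activity. The package is aimed at people analysing deeply
sequenced ATAC-Seq libraries of individual regulatory elements (promoters
and enhancers), where per-nucleotide coverage is high enough that single
binding sites appear as "protected regions" — short low-cut runs between
high-cut positions.

## The model

**Cut counting.** Each sequenced read reports one Tn5 insertion. Tn5
duplicates 9 bp at the insertion site, so the 5′ ends of a read pair map
8 bp apart; shifting +4 (plus strand) and −4 (minus strand) places both
cuts on the central nucleotide of the duplicated overhang. The widely used
+4/−5 shift does *not* do this — it leaves the two mates one base apart —
and is provided only to demonstrate that failure. Raw counts `y_i` are
normalized per sample to library size (cuts per million by default).

**Hexamer bias.** Tn5 prefers certain sequence motifs. From naked-DNA
(purified genomic DNA) libraries, the bias of hexamer *w* is

```
b(w) = pc(w) / p(w)
```

the ratio of *w*'s share of observed cuts to its share of genomic
positions, with the hexamer of a cut at position *i* read from the window
`[i−3, i+3)`. Three per-position corrections are implemented:

| method | formula | character |
|---|---|---|
| HINT-style | `x_i = (y_i + 1) / (ŷ_i · b̂(w(i)) + 1)` | 50-bp window mean `ŷ_i`, window-relative bias `b̂`; smooth, but adds one cut everywhere |
| BaGFoot-style | `x_i = y_i / b(w(i))` | single-nucleotide resolution; amplifies noise at low counts |
| Poisson-gated | `x_i = y_i / b(w(i))` only if `P(y_i; λ) < α/G` | corrects only counts incompatible with the genome-wide Poisson background `λ = library_size / G` (Bonferroni over `G` positions, `α = 0.01`) |

For `λ < 1` the gate reduces to a single count threshold `y*`; at the
study scale (`λ = 0.1`, `G = 2.73×10⁹`) `y* = 8`.

**Footprints.** On pooled raw counts, a protected region is a maximal run
of 5–50 positions with counts strictly below an element-specific threshold
(400 promoter, 100/40/200 for the three enhancers in the source study),
bordered on both sides by positions strictly above it. Accessibility
dynamics are summarized as per-bin means of normalized profiles over
uniform bins, site-adjacent change ratios, and in-site vs out-of-site
rank-sum comparisons.

**Reporter and qPCR formulas.** Single-cell reporter expression uses a
spiked internal standard: `b = f_PUER·f_samples/f_PUERs`,
`L = (f_sample − b)/(f_samples − b)`, anchored at 0 for background and 1
for the standard. ATAC-qPCR accessibility uses `ΔCq = Cq_enh − Cq_prom`
and `fold = 2^−ΔCq`, with technical replicates outside 1.5×IQR removed.

Everything is testable without external data through a fragment simulator
(`tn5foot.simulate`) that plants footprints and hexamer preferences with
known ground truth and emits properly paired SAM.

## Worked example

```python
import numpy as np
import tn5foot as t

genome = t.generate_genome(6000, gc_fraction=0.5, seed=7)
landscape = t.plant_landscape(genome, [((1000, 1012), 0.0), ((2500, 2530), 0.0)])
bias_model = t.BiasModel.with_preference("ACGTAC", 2.0)

profiles = []
for i, (sid, n) in enumerate([("t0", 30_000), ("t1", 40_000)]):
    fr = t.simulate_fragments(genome, landscape, bias_model, n_events=n,
                              seed=8 + i, sample_id=sid)
    counts = 2 * np.bincount(fr.events, minlength=genome.length)
    profiles.append(t.CutProfile("synth", 0, counts, counts.sum(), sample_id=sid))

pooled = t.pool_profiles(profiles)
print(f"pooled library size: {pooled.library_size:.0f} cuts")
print(f"coverage over [500, 4500): {t.coverage_per_nt(pooled, 500, 4500):.2f} cuts/nt")

naked = t.simulate_fragments(genome, t.plant_landscape(genome), bias_model,
                             60_000, seed=1007, sample_id="naked")
ncounts = 2 * np.bincount(naked.events, minlength=genome.length)
table = t.estimate_bias(t.CutProfile("synth", 0, ncounts, ncounts.sum()), genome.sequence)
print(f"estimated b(ACGTAC): {table['ACGTAC']:.3f}  (planted preference 2.0)")

regions = t.call_protected_regions(pooled, t.FootprintParams(threshold=8))
print(f"protected regions at T=8: {len(regions)}")
for r in regions:
    print(f"  [{r.start}, {r.end})  len={r.run_length}  "
          f"borders {r.left_count:.0f}/{r.right_count:.0f}")
res = t.compare_in_out_sites(pooled, [(1000, 1012), (2500, 2530)], alternative="less")
print(f"in-site vs out-of-site rank-sum p = {res.pvalue:.3g}")
```

Output:

```
pooled library size: 140000 cuts
coverage over [500, 4500): 23.25 cuts/nt
estimated b(ACGTAC): 2.298  (planted preference 2.0)
protected regions at T=8: 2
  [1000, 1012)  len=12  borders 42/18
  [2500, 2530)  len=30  borders 20/28
in-site vs out-of-site rank-sum p = 1.76e-29
```

Both planted footprints are recovered exactly, at their true coordinates
and lengths. The bias estimate is noisy here because a specific hexamer
occurs only a handful of times in a 6-kb genome; at 10⁶ events on a 50-kb
genome the estimate lands within a few percent of the planted 2.0
(see the test suite). The rank-sum p-value confirms that in-site
nucleotides carry far fewer cuts than out-of-site ones.

The same workflow is available from the shell:

```
tn5foot run --config config.yaml --out results/
tn5foot footprint --alignments a.sam --alignments b.sam \
    --region synth:500-4500 --threshold 8 --out footprints.bed
```

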