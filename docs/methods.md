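# Methods

This note records the scientific and numerical choices behind `tn5foot`:
what is modelled, which parameters matter, what the synthetic data does and
does not emulate, and where the design was genuinely open.

## Cut geometry and the +4/−4 shift

Tn5 transposition duplicates 9 bp at the insertion point. The read mapping
to the plus strand starts on the first nucleotide of the duplicated
overhang and the read mapping to the minus strand starts on the ninth, so
the two 5′ ends of a pair are always 8 bp apart. We define the *cut
position* as the central (fifth) nucleotide of the overhang. Shifting the
plus-strand 5′ end by +4 and the minus-strand 5′ end (its rightmost
aligned base, per SAM semantics) by −4 maps both mates of a pair onto that
single position. The conventional +4/−5 shift leaves the mates one base
apart, which halves the effective per-position signal and blurs footprint
borders; `count_cuts(..., shifts=(4, 5))` exists solely so this failure
can be demonstrated and regression-tested.

All coordinates are 0-based half-open internally; SAM is converted on
read, and BED/bedGraph output is half-open. A single internal convention
avoids off-by-one drift around the ±4 shift.

Retained reads are properly paired, mapped, primary, non-supplementary,
non-duplicate, and pass QC. `library_size` is the number of retained cuts
over the whole alignment source, not the profile interval, so that
normalization and the Poisson gate see genome-wide totals.

## Hexamer bias

The bias of hexamer *w* is `b(w) = pc(w)/p(w)`: its share of observed
naked-DNA cuts over its share of genomic positions. The hexamer attributed
to a cut at position *i* is the reference-strand sequence on `[i−3, i+3)`
— a symmetric window centred on the overhang midpoint. The registration
offset is a convention; what matters is that the simulator and the
estimator share it, so it lives in one module (`tn5foot.hexamers`) and is
recorded in `BiasTable` metadata. Cuts from both strands are attributed to
the reference-strand hexamer without reverse-complement splitting, because
cut positions are already strand-merged by the shift.

Hexamers present in the genome but receiving no cuts in a finite library
get `b = 0`. The table stores them flagged rather than failing outright;
the correctors raise only if a zero-bias hexamer is hit at a position with
nonzero counts selected for correction (`y = 0` corrects to 0 whatever the
bias). In deep naked-DNA libraries every hexamer receives cuts and the
strict positivity invariant holds.

## The three corrections

*HINT-style*: `x_i = (y_i + 1)/(ŷ_i · b̂(w(i)) + 1)`, where `ŷ_i` is the
mean of observed cuts over the 50-bp window `[i−25, i+24]` and `b̂(w(i))`
is the bias at *i* divided by the window's total bias. Implemented exactly
as this formula reads, including its known artifact: a profile of zeros
maps to a profile of ones. The formula multiplies a window *mean* by a
window-*relative* bias, which differs by a factor of 50 from "expected
cuts = window total × relative bias"; the alternate reading is available
as `window_statistic="sum"`. At interval edges the window truncates and
`b̂` renormalizes over the truncated window.

*BaGFoot-style*: `x_i = y_i / b(w(i))` everywhere. Exact per-nucleotide
correction, but divides small noisy counts by small biases, which can
manufacture spurious signal inside true footprints.

*Poisson-gated*: positions are corrected as in BaGFoot-style, but only
where the observed count is incompatible with the genome-wide background.
Counts are modelled as Poisson with `λ = library_size / G` (the pooled
library size for pooled profiles), and position *i* is corrected when
`P(y_i; λ) < α/G`, the familywise level `α = 0.01` Bonferroni-corrected
over the `G` genomic positions. The criterion uses the probability mass
function as such, not an upper-tail probability, and is evaluated in log
space. For `λ < 1` the PMF decreases monotonically in `y`, so the gate is
equivalent to a count threshold `y*` (`gate_threshold`); at `λ = 0.1`,
`G = 2.73×10⁹`, `α = 0.01` the threshold is `y* = 8`. For `λ ≥ 1` no
single threshold exists — low counts can also be "surprising" — and the
per-position test is applied as written. The correction is piecewise
exactly equal to BaGFoot-style above the gate and the identity below it,
which is tested as such.

## Footprint calling

A protected region is a maximal run of positions with counts strictly
below the threshold `T`, of length 5–50 bp, whose immediate neighbours on
both sides have counts strictly above `T`. Equality is unaddressed in
prose descriptions of such rules; here a position with count exactly `T`
terminates a run *and* disqualifies itself as a border, so the run is
discarded. Runs touching either end of the profile have no border and are
discarded. Calling operates on **raw pooled** counts: the element-specific
thresholds (400, 100, 40, 200 for the four elements of the source study)
are absolute cut counts, which only make sense before library-size
scaling. This choice — raw pooled for calling, normalized for dynamics —
is deliberate and worth flagging to users who pool differently-sized
libraries. Run detection is strictly consecutive: no internal position at
or above `T` is tolerated, however short the interruption.

The caller is verified against a brute-force enumerator on random
profiles, and against planted ground truth: depletion-0 footprints of
every length 5–50 are recovered completely at any threshold below the
flanking mean.

## Binning and dynamics

Uniform binning splits a region into `n_bins` contiguous bins whose widths
differ by at most 1 bp, the remainder going to the leading bins; per bin
and sample the mean normalized accessibility is reported. `n_bins` is
caller-specified per region (9 and 13 were used for the two enhancers in
the source study; no general rule is implied). Site-adjacent change
compares the mean absolute change between consecutive timepoints over
site ± flank against the remainder of the region; the default flank is
5 bp, flag-controlled, since "vicinity" has no canonical width. A
remainder with zero change yields NaN with a warning (undefined ratio)
rather than an exception. In-site vs out-of-site comparisons use the
Mann-Whitney U form of the rank-sum test (exact for small tie-free
samples), whose p-value is identical to Wilcoxon's W.

## Reporter and qPCR formulas

The flow-cytometry normalization uses medians throughout (distributions
are skewed and occasionally contaminated). The same estimated background
`b_sample` is subtracted from numerator and denominator of `L_sample`,
exactly as the formulas read — one might expect a standard-specific
background, but using a single estimate is what anchors `L` at exactly 0
for background and 1 for the internal standard, which the tests assert for
arbitrary medians. Bulk replicates (n = 6 in the source design) are
aggregated as mean ± standard error alongside per-replicate values.

ΔCq quartiles use linear interpolation between order statistics (the
"type 7" scheme), recorded in output metadata, with Tukey fences
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; the reading `|x − median| ≤ 1.5·IQR` is
available as `method="median"`. The fence is applied to per-replicate ΔCq
computed against the mean promoter Cq of the same biological sample.
Tukey refiltering is not idempotent in general — removing a point tightens
the fences, which can remove more — but for technical triplicates one pass
is structurally a fixed point, and the property test is scoped
accordingly.

## The synthetic-data generator

The simulator emulates exactly the features the analysis depends on:
paired-end transposition events with the 9-bp overhang geometry (both
mates of a pair land 8 bp apart and map back to one position under the
+4/−4 shift), a per-position accessibility landscape with planted 5–50 bp
protected regions of controllable depletion, a hexamer-level cutting
preference sharing the estimator's registration window, and multi-sample
series with differing library sizes. Events are drawn by inverse-CDF
sampling over the propensity × bias product under a single 64-bit seed;
positions whose hexamer window or 9-bp read span would exit the genome get
zero weight. Reads are written as properly paired, coordinate-sorted SAM
with MAPQ 60 and 9-bp reads covering the duplicated overhang.

It does **not** emulate sequencing errors, PCR duplicates, mappability
variation, fragment-length structure beyond the single-event pair, or
chromatin features like nucleosome phasing. Passing tests therefore
demonstrate the *arithmetic and inference machinery* — shift correctness,
bias recovery, corrector formulas, caller behaviour — not robustness to
real-library artifacts, which upstream alignment and duplicate-marking
must handle.

Simulation scales were chosen to keep every check comfortably inside
interactive runtimes while leaving no statistical ambiguity: 10⁴ events
for shift correctness (an exact, not statistical, property), 10⁶ events on
a 50-kb genome for bias recovery (the planted hexamer then receives ~10³
cuts, giving a relative standard error of a few percent; cuts arrive in
pairs, so effective sample size is the event count), and 2–4 × 10⁵ events
for footprint recall. Default pipeline parameters (6-kb genome, two
samples of 3–4 × 10⁴ events) give the pooled coverage regime (~20+
cuts/nt) in which the thresholds of the source study are meaningful.

## Degenerate inputs and numerical choices

Zero-variance profiles make Pearson correlation undefined and raise.
Normalization of a zero-library profile raises. `pearson_between`
smooths both profiles with the same truncated-window moving average
(odd windows only; even windows are rejected rather than silently
re-centred). Poisson PMFs are always evaluated via `logpmf` to avoid
underflow at genome-scale Bonferroni thresholds (α/G ≈ 10⁻¹²). The
bedGraph writer run-length-merges equal values and omits zero runs.
Manifest hashes are SHA-256 over file bytes; identical config + seed gives
hash-identical manifests, which the tests and the acceptance script verify
by running the full pipeline twice.

## Known limitations

- Bias estimation and correction assume the naked-DNA and chromatin
  libraries share one genome build; no liftover or masking is provided.
- The footprint caller has no explicit false-discovery control; its
  precision depends on coverage depth relative to the threshold, and the
  planted-recall tests measure recall, not precision, by construction.
- `λ ≥ 1` regimes gate low counts as well as high ones (a direct
  consequence of using the PMF as printed); users correcting very deep
  pooled profiles over small regions should check `PoissonGate.lam`.
- The CLI consumes single-contig FASTA for simplicity; multi-contig
  analyses should use the library API.
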