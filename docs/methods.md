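# Methods

This note documents the models, conventions, parameters and design decisions
behind `ucre`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and overlap semantics

All internal coordinates are 0-based half-open (BED convention); VCF
positions are converted on read (`pos − 1`). The overlap predicate used
everywhere is "any shared base" (≥1 bp) — the default of the standard
interval tools — with no reciprocal-fraction option anywhere in the
pipeline. Abutting half-open intervals do not overlap. Windowed overlap
extends the query by a symmetric flank (clamped at chromosome bounds) but
always reports the original coordinates. Interval sets iterate in
(chromosome, start, end, name) order, so every written artifact diffs
cleanly between runs; writers emit sorted output.

Signed element-to-point distance is 0 inside the interval, `point − start`
(negative) left of it, and `point − end` at or beyond the exclusive end.
Binned distance distributions use the magnitude with bins 0–5 kb, 5–50 kb,
50–500 kb, >500 kb.

## Peak calling

Accessibility and histone tracks arrive as pre-normalised bedGraph step
functions, so peak calling is plain thresholding, not an approximation of a
background model: maximal runs of bases with value ≥ cutoff, sub-threshold
gaps ≤ `max_gap` closed, runs < `min_length` discarded. Defaults follow the
narrow-peak caller family: `min_length=200`, `max_gap=30`; cutoffs are 0.4
for single-cell accessibility signal and 20 for histone-mark signal. The
summit is the leftmost base attaining the run maximum (determinism), and the
carried score is the run maximum. Note that the peak *count* is provably
monotone in cutoff and `min_length` but not in `max_gap` (closing a gap
between two passing runs lowers the count; merging two sub-length runs can
raise it), so only the true directions are asserted as invariants.

## Ultraconservation scanning

An element is a maximal reference interval of length ≥ 201 bp ("longer than
200 bp" read strictly) whose alignment columns show identity ≥ 0.95. Gap
columns count as mismatches; a column consumes a reference coordinate only
when the reference base is non-gap, so partner insertions penalise identity
without extending the reference span. Because identity is not monotone in
window length, maximality needs a tie-break: among overlapping qualifying
windows the longest wins, ties to the leftmost, applied greedily in
descending length. At identity 1.0 this provably reduces to the maximal
perfect-match runs. The implementation sweeps lengths with prefix sums; the
test oracle enumerates every window independently.

## Regulatory domains

Basal domain: [TSS−5000, TSS+1000) on the + strand, mirrored on −, clamped
to the chromosome. The extension on each side reaches the nearer of (a) the
closest other gene's basal boundary on that side and (b) 1 Mb from the basal
boundary; a foreign basal domain overlapping the gene's own basal domain on
a side suppresses extension on that side entirely. Basal domains are never
truncated — only extensions are. Curated long-range domains (the mechanism
behind exceptions like globin-locus control regions) are supported as an
optional per-gene override of the extended interval. The per-base membership
rule ("within 1 Mb of the basal domain and not beyond the nearest flanking
basal boundary") is the oracle the builder is tested against.

Expression filtering keeps a target gene iff TPM ≥ 0.5 in at least one
stage: the source definition of *non-expression* is TPM < 0.5, so exactly
0.5 counts as expressed. TAD consistency requires one TAD to overlap the
element by ≥1 bp *and* contain the TSS (half-open, so a TSS at the exclusive
TAD end is outside). Expression signatures take, per gene, the clusters
strictly above that gene's 80th percentile across clusters (linear
interpolation between order statistics); a constant gene therefore has an
empty signature rather than an error. The percentile is computed per gene
across clusters (the alternative per-cluster-across-genes reading was
considered and not implemented). Peak-to-gene linkages qualify at
correlation strictly above 0.4.

## Variant frequency bins

Bins partition [0,1] ∪ {absent}: ultrarare = absent from the reference
database (an explicit flag, distinct from frequency-unknown, which is an
error and never defaulted to 0); very rare MAF < 0.1%; rare 0.1% ≤ MAF <
0.5%; low frequency 0.5% ≤ MAF < 5%; common MAF ≥ 5%. MAF is the alternate
allele frequency folded at 0.5. The rare-variant filter keeps absent-or-MAF
< 0.5% variants with zero reference homozygotes. Structural variants count
as inside an element on any overlap (a large duplication *spanning* an
element is a hit), not containment. The search space keeps hits whose
element state is at least `marked` and whose target set intersects the
disease-gene table.

## Constraint statistics

The background is 200 random fragments of exactly 350 bp, sampled uniformly
over the genome with a seeded generator, rejecting overlaps with the
exclusion set (the elements themselves, plus assembly gaps when supplied);
fragments may overlap each other, mirroring the behaviour of standard
random-fragment utilities. Flanks are ±200 bp per element, clipped so no
flank base lies in any element body.

Constraint comparisons sample *per base* (a region contributes its length in
observations), matching a nucleotide-resolution score; a per-region-mean
mode exists for sensitivity analysis. Kruskal–Wallis uses mid-ranks with the
tie correction `H / (1 − Σ(t³−t)/(N³−N))` and a χ² reference with k−1
degrees of freedom; an all-identical sample returns H = 0, p = 1 rather than
0/0. Dunn's z uses the pooled-variance form with the same tie term,
two-sided normal p-values and Bonferroni over k(k−1)/2 pairs (adjusted p
capped at 1). The background-suitability check (TSS-distance comparability
of fragments vs elements) reuses the same rank machinery with k = 2 rather
than introducing a second test.

Spectrum normalisation is emitted in two forms: the within-class proportion
ratio per bin, and a per-bp **density ratio** (count/bp inside elements
divided by count/bp in the background) with a delta-method standard error.
Under the generator's rate model — common-variant rate multiplied by a
depletion factor *d* inside elements — the density ratio has expectation
exactly *d*, whereas the proportion ratio has expectation d/(1−c+dc) for
background common share *c*; recovery tests therefore use the density ratio.

## The synthetic study system

The generator plants, on a 2×2 Mb genome with 60 genes and 150 elements:

* nested activity fractions 0.34 / 0.19 / 0.026 / 0.008 of elements that are
  open / marked / H3K27ac-active / adult-sustained, matching the observed
  ratios of the study system this emulates (≈⅓ of elements open; marked
  states a nested minority), with 80% of open elements supported by both
  accessibility sources;
* accessibility and mark peaks as signal plateaus above the respective
  cutoffs covering the planted elements, plus Poisson background peaks that
  deliberately avoid element bodies (and their ±250 bp mark window) so the
  planted truth stays exact at any background rate;
* genes spaced ≥20 kb so basal domains never overlap, making the
  closed-form sorted-neighbour domain rule exact — the truth table's edges
  come from that closed form, not from the pipeline's domain builder;
* 82% of target genes expressed (high TPM in one stage, <0.5 elsewhere);
  cluster expression with exact baselines and ≤2 high clusters per gene so
  planted signatures are recovered exactly by the 80th-percentile rule;
  ~54% of open elements planted concordant;
* TADs tiled with mean size 200 kb; per-edge TAD co-containment recorded by
  a direct scan at generation time;
* a variant cohort at 0.008 variants/bp with bin shares (0.50, 0.15, 0.10,
  0.10, 0.15) from ultrarare to common, the common-bin rate multiplied by
  d = 0.2 inside elements, unique positions per chromosome, 60 cases (56%
  unsolved), and 5 structural variants, some spanning elements;
* per-base i.i.d. N(0,1) constraint scores shifted by −δ (default 0.5)
  inside elements and −δ/2 in flanks, served by a deterministic
  random-access procedural track (block-keyed RNG). Per-base independence is
  what makes the rank tests exactly calibrated under the null; a windowed
  score would duplicate values across bases and invalidate the test's
  nominal level. The file bundle records the constraint model in its
  manifest instead of materialising a genome-wide per-base bedGraph;
  bedGraph-backed constraint tracks are fully supported for real data.

What the generator does **not** emulate: sequence content (GC, repeats),
read-level noise, doublets/batch effects in the single-cell data, linkage
between variants, or realistic TAD nesting. Passing tests therefore
demonstrate correctness of the integration logic and calibration of the
statistics under the stated model — not robustness to the artefacts of real
assays.

A single global seed fans out to per-component streams (placement, states,
tracks, expression, linkages, disease table, variants, labels, TADs), so a
component can be regenerated independently; the constraint calibration tests
exploit this by redrawing only the score track. All problem sizes above were
chosen as the package's default study conditions; the statistical-recovery
tests run at exactly these defaults.

## Numerical and I/O choices

* bedGraph and variant-TSV writers emit full-precision floats (`repr`) so
  read∘write is the identity; VCF `AF` is a single-precision Float per the
  spec of that format, and round-trips to ~7 significant digits.
* Sorting ties are broken by name, lexicographically.
* The positive-proportion of a query set against the validated-enhancer
  table is reported as 0/0 with an explicit `undefined` flag when nothing
  overlaps, never as 0. Tissue distributions are emitted both per
  element–tissue mention and per element (weight split across tissues),
  since either reading of a proportional breakdown is defensible.
* The count of elements "with at least one assessed feature" is reported
  both over all ten assessed chromatin features and restricted to activating
  marks, since repressive marks arguably do not indicate enhancer activity.
* Pipeline reports carry a config hash, the seed and the package version;
  reruns with identical config and inputs are byte-identical.

## Known limitations

* The scanner's maximality rule (longest-first greedy) is one defensible
  formalisation of "maximal ultraconserved segment"; catalogues built with a
  different segment-extension rule can differ at block boundaries.
* `identify_open_ucnes` treats any accessibility evidence as "open" without
  peak-strength weighting.
* Dunn's test is computed unconditionally; no gatekeeping on the omnibus
  test is applied (the calibration tests treat the omnibus as the type-I
  reference).
* The per-base constraint sampling treats bases as independent draws; real
  constraint tracks are autocorrelated along the genome, which inflates the
  effective significance of rank tests on real data. This matches how such
  comparisons are commonly done, but p-values on real tracks should be read
  qualitatively.
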