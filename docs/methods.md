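# Methods

This note records the statistical model behind `ekaryo`, the meaning and
default of every tunable parameter, the scope of the synthetic generator,
and the numerical choices that a reimplementation would need to reproduce
results exactly.

## Model

A copy-number alteration (CNA) spanning a chromosomal region shifts the
log2 expression of most genes in the region by an approximately constant
amount Δ, on top of per-gene biological/technical noise and sample-wide
effects. After centring each gene on a diploid reference, a sample's
profile along the genome is modelled as piecewise constant plus noise;
segmentation recovers the pieces, and thresholds on segment mean, length
and significance convert them into ternary calls (−1 loss, 0 neutral,
+1 gain). At typical array noise (σ ≈ 0.2 log2 units per gene), a
whole-chromosome gain of log2(3/2) ≈ 0.32 across hundreds of genes
produces a mean shift many standard errors wide — individually invisible,
jointly unambiguous.

## Preprocessing (`ekaryo.preprocess`)

Fixed order of operations; each step's product feeds the next:

1. **Probe collapsing** — probes mapping to the same gene are averaged
   (arithmetic mean of values and of positions); probes without genomic
   location are dropped; a gene with probes on two chromosomes is an
   error naming the gene.
2. **log2** — applied when the matrix looks linear-scale (max value > 50);
   override with `log_transform_needed`.
3. **Flooring** — values below `floor_value` (default **6.5**) are raised
   to it; a value at/below the floor counts as "not expressed".
4. **Expression filter** — a gene at the floor in strictly more than
   `unexpressed_sample_fraction` (default **0.20**) of a batch's samples
   is dropped. An input in which this removes every gene is an error.
5. **Variance filter** — the top ⌊`variable_fraction_removed` · n⌋
   (default **0.10**) most variable genes are dropped (variance across
   samples; ties broken by gene id for determinism). Note this criterion
   is *relative*: re-running preprocessing on an already-preprocessed
   matrix would trim another decile; a strict re-run no-op requires
   setting the fraction to 0.
6. **Centring** — per gene, subtract the median over reference samples
   (`tissue_class == "normal"` when present) or the per-batch median
   otherwise. The result is the comparative matrix.

## Segmentation and calling (`ekaryo.segmentation`)

Per sample and chromosome, values are winsorized at quantile
`winsorize_quantile` (default **0.001**) and segmented by exact dynamic
programming minimising

    Σ_segments SSE(segment) + penalty · γ · (#breakpoints)

with `penalty` default **14** (sensible range 12–18) and the noise scale
γ = (median|Δx| / (√2·0.6745))², the squared robust (MAD-based) estimate
of the per-gene noise σ from successive differences, floored at 1e−12 so
a noiseless input still segments. The DP is O(n²) with prefix sums and is
validated against brute-force enumeration in the test suite.

A segment is called ±1 iff all three hold:

- |mean| ≥ `least_allowed_deviation` (default **0.25**, range 0.15–0.4);
- length ≥ `least_allowed_aberration_size` genes (default **50**, 50–80);
- one-sample t-test of the segment's (winsorized) values against 0 gives
  p < `threshold` (default **0.01**); `threshold=None` disables the gate.
  A zero-variance segment counts as significant iff its value is nonzero.

Per-sample classification merges maximal runs of adjacent same-sign
called segments within a chromosome into discrete aberrations:
0 → `diploid`, 1 → `single_CNA`, ≥2 → `multiple_CNA`. A moving-average
profile (window **200** genes, symmetrically shrinking at chromosome
ends) supports visual inspection. Segments are exported/read as SEG.

## Component correction and autocorrelation (`ekaryo.fgmp`)

The top *k* (default **25**) principal axes of the gene-centred reference
compendium are taken as transcriptional components (SVD; loadings
orthonormal, ordered by explained variance; genes are centred, not
scaled, to preserve dosage effects). Tumour profiles are replaced by
their residual after orthogonal projection onto the span of the loadings
restricted to shared genes (re-orthonormalized by QR; < 50% gene overlap
is an error). The projection is idempotent and residuals are orthogonal
to every loading.

The autocorrelation instability score is the lag-`lag` (default **10**)
Pearson correlation of the genome-ordered profile with itself, computed
*within* chromosomes and combined by a length-weighted average; windows
never straddle chromosome boundaries. Consequence: a whole-chromosome
shift is a constant the correlation removes — the score responds to
sub-chromosomal structure (this matters when constructing validation
cohorts; see Limitations). Zero-variance input yields 0 with a warning.

## Instability metrics (`ekaryo.instability`)

Per sample: aberration count, altered-gene fraction (genes in called
segments / total genes) and optionally the autocorrelation score.
Group comparisons: prevalence tables use the χ² test of independence
without continuity correction (Fisher's exact test when any group has
n < 10, two groups only; Yates correction available as a flag); score
distributions use Mann–Whitney (two groups) or Kruskal–Wallis with an
all-pairs Dunn post-hoc (tie-corrected z statistics, Bonferroni over the
k(k−1)/2 pairs). The false-call bound is the exact one-sided
Clopper–Pearson upper limit, `beta.ppf(conf, k+1, n−k)`; for 0 false
calls in n samples this is 1 − (1−conf)^(1/n).

## Recurrence and arm calls (`ekaryo.recurrence`)

Segments are projected onto cytobands: each band takes the call of the
segment(s) covering the largest fraction of it; exact ties resolve to 0.
Within one model, a (band, direction) is recurrent if its frequency
exceeds `prevalence_cutoff` (default **0.10**, strict) or if the
one-sided binomial tail P[Bin(N, p_c) ≥ K] is below `alpha` (default
**0.05**) after Bonferroni correction over the bands tested in that
direction (gains and losses corrected separately). The background rate
pools all other bands: p_c = (direction events elsewhere)/(N·(n_bands−1)).
p_c = 0 with K > 0 yields p = 0 and is flagged (`zero_background`).
Model specificity is a χ² test on the models × event/no-event table,
Bonferroni over all testable (band, direction) pairs in a scan, with the
event attributed to the highest-frequency model.

For segmented DNA input: per sample, the length-weighted median log2
ratio is subtracted, values map to relative copies r → 2·2^r − 2 clamped
to ±`cap` (default **1.5**), and each arm is called ±1 when the
length-weighted median of intersected segments strictly exceeds
±`threshold` (default **0.1**; an exactly-threshold median is 0). Arms
with less than `min_covered_fraction` (default **0.5**) of their length
covered are reported missing. Calls are invariant to value-preserving
re-segmentation.

## Cross-species narrowing (`ekaryo.crossspecies`)

Synteny blocks map intervals by linear interpolation (orientation-aware);
adjacent same-pair blocks separated by < 1 Mb on both sides can be
merged. A species-A region maps to species-B intervals (uncovered parts
reported), which are intersected with species-B recurrent intervals to
give the critical region; reduction percentages are reported for both
species. Candidate genes are orthologues inside the critical region
whose species-A differential expression is significant (adjusted p <
alpha) and direction-concordant, sorted by |effect|.

The information coefficient is IC = sign(r)·√(1 − exp(−2·MI)) with r the
Pearson correlation and MI the differential mutual information from
bivariate Gaussian kernel density estimates (Silverman bandwidth),
evaluated at the sample points. The plug-in MI is positively biased even
under independence, which the rescaling would inflate to |IC| ≈ 0.15–0.25
at n = 2000; the implementation therefore subtracts the mean plug-in MI
over `n_null` (default **5**) permutations of y before rescaling
(clamped at 0). For bivariate Gaussian data MI = −½·log(1−ρ²), so IC
converges to ρ; the debiased estimator is within 0.1 of ρ at n = 2000.
Significance comes from a permutation test on |IC| with the add-one rule.

## Synthetic generator (`ekaryo.synthetic`)

Expression = baseline (default 7.0) + per-sample offset (sd 0.05) +
shared component structure (optional; loadings shared with a compendium
when supplied) + per-gene noise (sd `gene_noise_sd`, default 0.2) +
regional shifts, floored at 6.5. Default event magnitudes follow
single-copy arithmetic: gains +log2(3/2) ≈ 0.32, losses −log2(2/1) ≈
−0.58. In auto mode each sample carries one whole-chromosome event with
probability `aberration_prevalence`; `exact_prevalence=True` instead
plants events in exactly round(p·n) samples, removing binomial noise in
the ground truth so that detector studies measure the detector.
An explicit `event_catalogue` supports chromosome, cytoband or
(chrom, start, end) regions with per-event probability and shift.
Companion generators produce reference compendia (no CNAs), segmented
DNA profiles with arm events and value-preserving extra splits, and toy
synteny/orthology maps. Ground truth (carriers, per-event assignments,
band frequencies) is returned alongside every cohort.

Scope: the generator models additive log2 shifts with Gaussian noise; it
does not simulate platform-specific probe effects, GC waves, tumour
purity dilution, subclonality, or correlated gene programs beyond the
explicit shared components.

## Numerical choices

- Winsorization uses `np.quantile(..., method='nearest')`: it clamps to
  observed values and is reflection-symmetric (methods like
  `inverted_cdf` are not, which would make results depend on the sign
  convention of the input).
- The PCF penalty scale γ is floored at 1e−12 so noiseless inputs remain
  segmentable; the DP objective is exact, not heuristic.
- Variance-filter ties are broken by gene id (string order) so gene
  ordering of the input cannot change results.
- All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; derived seeds stay below 2³¹.
- Chromosome names are normalized internally to bare names ("1", "X");
  file writers re-emit the conventional dialect of each format.

## Limitations

- Detection power depends on the shift-to-noise ratio: at the default
  calling deviation 0.25, single-copy gains (+0.32) sit close to the
  threshold and sample-wide offsets (sd 0.05) can push a carrier below
  it; validation setups use |shift| 0.4 where near-certain detection is
  the intent.
- The autocorrelation score cannot see whole-chromosome events (constant
  within-chromosome shifts cancel in the correlation); burden ranking by
  this score requires sub-chromosomal structure.
- Batch-median centring assumes aberrations are rare per gene; above
  ~50% prevalence the median tracks carriers and signal inverts into the
  minority — use a normal reference for high-burden cohorts.
- The binomial recurrence test conditions on the pooled background rate
  estimated from the same matrix; with very few events the p_c = 0
  degenerate case is flagged rather than modelled.
- Problem sizes are package choices scaled for desk-top validation
  (thousands of genes, hundreds of samples); nothing in the algorithms
  limits larger inputs, but the O(n²) per-chromosome DP dominates run
  time for very long chromosomes.
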