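# ekaryo

Expression-based karyotyping (e-karyotyping) of tumour cohorts: inferring
chromosomal copy-number alterations (CNAs) from coordinated regional biases
in gene-expression profiles, without DNA data.

A gained chromosome raises the measured expression of most genes on it by a
small, roughly constant log2 amount; a lost one lowers it. Individually the
shifts drown in biological noise, but jointly — hundreds of neighbouring
genes moving the same way — they are detectable by segmentation. `ekaryo`
implements that inference chain end to end:

- **Preprocessing** (`ekaryo.preprocess`) — collapse probes to genes, log2
  transform, floor low expression, drop unexpressed and hyper-variable
  genes, and centre each gene on a reference (normal samples when present,
  otherwise the per-batch median) to form the *comparative matrix*.
- **Segmentation and calling** (`ekaryo.segmentation`) — exact penalized
  piecewise-constant-fit (PCF) segmentation of each sample along the
  genome; segments are called gain/loss when they are long enough, deviate
  enough, and pass a mean-versus-zero significance check; samples are
  classified diploid / single CNA / multiple CNA.
- **Transcriptional-component correction** (`ekaryo.fgmp`) — fit the
  dominant expression components on a non-cancer compendium and residualize
  tumour profiles against them, so that what remains tracks copy number;
  also provides the lag-10 autocorrelation instability score.
- **Instability metrics** (`ekaryo.instability`) — per-sample aberration
  counts, altered-gene fractions and autocorrelation scores, with the
  group-comparison statistics used on such tables (χ²/Fisher,
  Mann–Whitney, Kruskal–Wallis + Dunn) and an exact binomial
  false-discovery bound.
- **Recurrence analysis** (`ekaryo.recurrence`) — project segments onto
  cytobands, flag recurrent events by a >10% prevalence rule or a
  Bonferroni-corrected binomial test against the pooled background rate,
  test model specificity by χ², and call arm-level events from segmented
  DNA copy number (±0.1 rule on length-weighted arm medians).
- **Cross-species narrowing** (`ekaryo.crossspecies`) — map recurrent
  regions between species through synteny blocks, intersect with the other
  species' recurrent regions to obtain a smaller critical region, rank
  direction-concordant orthologue candidates, and quantify associations
  with a kernel-based information coefficient.
- **Synthetic data with ground truth** (`ekaryo.synthetic`) — genomes,
  expression cohorts with embedded CNAs, reference compendia with shared
  components, segmented DNA profiles and toy synteny maps, so every stage
  can be validated against known truth.
- **Pipeline and CLI** (`ekaryo.pipeline`, `ekaryo` command) — a validated,
  manifest-writing end-to-end run from one YAML config, plus per-stage
  subcommands.

## Worked example

```python
from ekaryo import (CohortSpec, PCFParams, classify_samples, make_genome,
                    preprocess, segment_cohort, simulate_cohort)

genome = make_genome(n_chromosomes=5, genes_per_chromosome=300,
                     cytobands_per_chromosome=8, seed=0)
spec = CohortSpec(n_samples=40, aberration_prevalence=0.5,
                  gain_shift=0.4, loss_shift=-0.4, seed=11)
cohort, truth = simulate_cohort(genome, spec)

comparative = preprocess(cohort)
segments = segment_cohort(comparative, PCFParams())
classes = classify_samples(segments)
```

Running `python examples/01_simulate_and_segment.py` (exactly this
analysis, plus the comparison against ground truth) prints:

```
simulated 40 samples x 1500 genes; true prevalence 0.50
called 20 aberrant segments
sensitivity 1.00, false positives 0
classification
diploid       20
single_CNA    20
```

The other scripts in `examples/` walk through component correction
(`02`), recurrence and model specificity (`03`), arm-level calling
(`04`) and cross-species narrowing with the information coefficient
(`05`); each prints a short self-checking narrative.

The same chain is available from the shell:

```sh
ekaryo simulate --n-samples 40 --prevalence 0.5 --outdir sim/
ekaryo preprocess sim/expression.tsv --samples sim/samples.tsv --out comp.tsv
ekaryo segment comp.tsv --samples sim/samples.tsv --out segments.seg
ekaryo recur segments.seg --cytobands sim/cytobands.tsv \
    --samples sim/samples.tsv --outdir recurrence/
```

or as one validated run: `ekaryo run config.yaml` (see
`ekaryo.pipeline.RunConfig` for the YAML schema).

## Documentation

`docs/methods.md` describes the statistical model, every tunable parameter
with its default and rationale, the synthetic generator's scope, and the
numerical choices and limitations.
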