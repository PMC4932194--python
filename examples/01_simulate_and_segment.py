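"""Simulate a tumour cohort with known aberrations, then recover them.

A synthetic genome of 5 chromosomes carries a cohort of 40 tumours in which
half the samples harbour one whole-chromosome gain or loss.  The script
preprocesses the expression matrix into a comparative matrix, segments every
sample with the penalized piecewise-constant fit, and compares the detected
carriers against the generator's ground truth.
"""

from ekaryo import (CohortSpec, PCFParams, classify_samples, make_genome,
                    preprocess, segment_cohort, simulate_cohort)

genome = make_genome(n_chromosomes=5, genes_per_chromosome=300,
                     cytobands_per_chromosome=8, seed=0)
spec = CohortSpec(n_samples=40, aberration_prevalence=0.5,
                  gain_shift=0.4, loss_shift=-0.4, seed=11)
cohort, truth = simulate_cohort(genome, spec)
print(f"simulated {cohort.n_samples} samples x {cohort.n_genes} genes; "
      f"true prevalence {truth.true_prevalence:.2f}")

comparative = preprocess(cohort)
segments = segment_cohort(comparative, PCFParams())
classes = classify_samples(segments).set_index("sample")

carriers = set(truth.carriers())
detected = {s for s in classes.index if classes.loc[s, "n_aberrations"] >= 1}
print(f"called {int((segments.segments['call'] != 0).sum())} aberrant segments")
print(f"sensitivity {len(carriers & detected) / len(carriers):.2f}, "
      f"false positives {len(detected - carriers)}")
print(classes["classification"].value_counts().to_string())
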