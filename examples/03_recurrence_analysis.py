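"""Find recurrent and model-specific aberrations across two tumour models.

Two cohorts from different models are simulated, segmented, and projected
onto cytobands.  Recurrence within each model combines a >10% prevalence
rule with a one-sided binomial test against the pooled background rate;
a χ² scan then asks which events are specific to one model.
"""

import pandas as pd

from ekaryo import (CNAEvent, CohortSpec, ExpressionCohort, PCFParams,
                    make_genome, preprocess, recurrence_test, segment_cohort,
                    segments_to_cytobands, simulate_cohort, specificity_scan)

genome = make_genome(5, 300, 8, seed=0)
shared = CNAEvent(region="1", direction="gain", probability=0.4, shift=0.4)
private = {"modelA": CNAEvent(region="2", direction="gain",
                              probability=0.6, shift=0.4),
           "modelB": CNAEvent(region="4", direction="loss",
                              probability=0.6, shift=0.4)}
parts = []
for mi, model in enumerate(("modelA", "modelB")):
    spec = CohortSpec(n_samples=25, event_catalogue=[shared, private[model]],
                      model_label=model, batch_id=f"b{mi}", seed=20 + mi)
    parts.append(simulate_cohort(genome, spec)[0])
cohort = ExpressionCohort(pd.concat([p.values for p in parts], axis=1),
                          parts[0].genes,
                          pd.concat([p.samples for p in parts],
                                    ignore_index=True))

segments = segment_cohort(preprocess(cohort), PCFParams())
labels = cohort.samples.set_index("sample_id")["model_label"]
matrix = segments_to_cytobands(segments, genome.cytobands, labels)

for model in ("modelA", "modelB"):
    sub = matrix.restrict_model(model)
    rec = pd.concat([recurrence_test(sub, d) for d in ("gain", "loss")])
    hits = rec[rec["recurrent"]]
    print(f"{model}: {len(hits)} recurrent (band, direction) events, e.g.")
    print(hits[["cytoband", "direction", "K", "N", "frequency",
                "p_bonferroni"]].head(3).to_string(index=False))

scan = specificity_scan(matrix)
specific = scan[scan["model_specific"]]
print(f"\nmodel-specific events: {len(specific)} of {len(scan)} tested")
if len(specific):
    print(specific[["cytoband", "direction", "attributed_model",
                    "p_bonferroni"]].head(5).to_string(index=False))
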