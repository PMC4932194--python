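"""Expression preprocessing: probe collapsing, flooring, filtering, centring.

The fixed order is: drop unlocated probes → collapse probes to genes →
log2 (if the matrix looks linear) → floor at the platform detection limit →
drop genes unexpressed in more than 20% of samples within a batch → drop
the 10% most variable genes → subtract the per-gene median of the normal
reference samples (or of the whole batch when no normals exist), yielding
the comparative matrix that segmentation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .genome import sort_genome_order

__all__ = [
    "PreprocessParams", "collapse_probesets", "maybe_log2",
    "floor_expression", "filter_unexpressed", "filter_most_variable",
    "center_to_reference", "preprocess",
]


@dataclass
class PreprocessParams:
    """Platform-dependent knobs of the preprocessing chain.

    ``floor_value``: detection-limit floor in log2 units (6.5–7 for
    Affymetrix/Illumina-style intensities, −0.5 for Agilent-style ratios).
    ``unexpressed_sample_fraction``: a gene is dropped when the fraction of
    samples at the floor exceeds this (strictly), per batch.
    ``variable_fraction_removed``: fraction of the most variable genes
    removed to reduce expression noise.
    """
    floor_value: float = 6.5
    unexpressed_sample_fraction: float = 0.20
    variable_fraction_removed: float = 0.10
    log_transform_needed: bool | None = None   # None = auto-detect

    def __post_init__(self):
        for f in (self.unexpressed_sample_fraction, self.variable_fraction_removed):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def collapse_probesets(probe_values: pd.DataFrame,
                       probe_map: pd.DataFrame,
                       samples: pd.DataFrame | None = None) -> ExpressionCohort:
    """Average multi-probe genes into one row per gene.

    ``probe_values`` is probe × sample (index = probe_id); ``probe_map``
    has columns ``probe_id``, ``gene_id``, ``chromosome``, ``position``.
    Probes without an annotated location are dropped first.  The collapsed
    value and representative position are the arithmetic means over the
    gene's probes; rows come back in genome order.
    """
    if probe_map.empty:
        raise ValueError("empty probe map")
    pm = probe_map.dropna(subset=["chromosome", "position"]).copy()
    pm = pm[pm["probe_id"].isin(probe_values.index)]
    if pm.empty:
        raise ValueError("no mappable probes")
    pm["chromosome"] = pm["chromosome"].astype(str)
    multi = pm.groupby("gene_id")["chromosome"].nunique()
    bad = multi[multi > 1].index.tolist()
    if bad:
        raise ValueError(f"gene(s) with probes on different chromosomes: {bad}")
    vals = probe_values.loc[pm["probe_id"]].copy()
    vals.index = pd.Index(pm["gene_id"].values, name="gene_id")
    gene_vals = vals.groupby(level=0).mean()
    ann = pm.groupby("gene_id").agg(chromosome=("chromosome", "first"),
                                    position=("position", "mean")).reset_index()
    ann = sort_genome_order(ann)
    gene_vals = gene_vals.loc[ann["gene_id"]]
    if samples is None:
        samples = pd.DataFrame({"sample_id": list(gene_vals.columns),
                                "tissue_class": "tumour",
                                "model_label": "unknown", "batch_id": "batch0"})
    return ExpressionCohort(values=gene_vals, genes=ann, samples=samples)


def maybe_log2(cohort: ExpressionCohort, needed: bool | None = None,
               linear_threshold: float = 50.0) -> ExpressionCohort:
    """log2-transform if the matrix looks linear-scale (max value above
    ``linear_threshold``) or when ``needed`` says so explicitly."""
    if needed is None:
        needed = float(np.nanmax(cohort.values.values)) > linear_threshold
    if not needed:
        return cohort
    vals = np.log2(np.maximum(cohort.values.values, 1e-12))
    return replace(cohort, values=pd.DataFrame(vals, index=cohort.values.index,
                                               columns=cohort.values.columns))


def floor_expression(cohort: ExpressionCohort, floor_value: float) -> ExpressionCohort:
    """Raise every value below the detection-limit floor to it (idempotent)."""
    if not np.isfinite(floor_value):
        if floor_value == -np.inf:
            return cohort
        raise ValueError("floor_value must be finite or -inf")
    vals = cohort.values.clip(lower=floor_value)
    return replace(cohort, values=vals)


def filter_unexpressed(cohort: ExpressionCohort,
                       params: PreprocessParams) -> ExpressionCohort:
    """Drop genes at the floor in more than the allowed fraction of samples.

    "Not expressed" means value ≤ floor after flooring (the floor is the
    platform detection threshold).  Evaluated within each batch; a gene
    failing in any batch is dropped.
    """
    at_floor = cohort.values.values <= params.floor_value
    drop = np.zeros(cohort.n_genes, dtype=bool)
    cols = np.asarray(cohort.values.columns)
    for batch, grp in cohort.samples.groupby("batch_id"):
        idx = np.isin(cols, grp["sample_id"].values)
        frac = at_floor[:, idx].mean(axis=1)
        drop |= frac > params.unexpressed_sample_fraction
    if drop.all():
        raise ValueError("expression filter removed every gene; "
                         "review floor_value / unexpressed_sample_fraction")
    return cohort.with_genes(~drop)


def filter_most_variable(cohort: ExpressionCohort,
                         params: PreprocessParams) -> ExpressionCohort:
    """Remove the top ⌊fraction × n⌋ genes by cross-sample variance
    (ties broken by gene_id order)."""
    n_remove = int(np.floor(params.variable_fraction_removed * cohort.n_genes))
    if n_remove == 0:
        return cohort
    var = cohort.values.var(axis=1, ddof=1).values
    order = np.lexsort((np.asarray(cohort.genes["gene_id"], dtype=str), -var))
    drop_idx = order[:n_remove]
    keep = np.ones(cohort.n_genes, dtype=bool)
    keep[drop_idx] = False
    return cohort.with_genes(keep)


def center_to_reference(cohort: ExpressionCohort,
                        reference_sample_ids: list[str] | None = None
                        ) -> ExpressionCohort:
    """Subtract the per-gene median over the reference samples.

    With explicit ``reference_sample_ids`` (typically the normal tissue
    samples) the per-gene median over that set becomes 0; with None the
    whole batch is its own reference.  The result is the comparative
    matrix on which regional biases are detected.
    """
    if reference_sample_ids is not None:
        if len(reference_sample_ids) == 0:
            raise ValueError("empty reference sample list")
        missing = set(reference_sample_ids) - set(cohort.values.columns)
        if missing:
            raise ValueError(f"reference samples absent from matrix: {sorted(missing)}")
        ref = cohort.values[list(reference_sample_ids)]
        mode = "normals"
    else:
        ref = cohort.values
        mode = "batch_median"
    med = ref.median(axis=1)
    vals = cohort.values.sub(med, axis=0)
    return replace(cohort, values=vals, reference_mode=mode)


def preprocess(cohort: ExpressionCohort,
               params: PreprocessParams | None = None,
               reference_sample_ids: list[str] | None = "auto"
               ) -> ExpressionCohort:
    """Run the full chain in its fixed order and return the comparative matrix.

    ``reference_sample_ids="auto"`` uses the cohort's normal-tissue samples
    when present, otherwise the whole batch.
    """
    params = params or PreprocessParams()
    out = cohort.sorted_genome_order()
    out = maybe_log2(out, needed=params.log_transform_needed)
    out = floor_expression(out, params.floor_value)
    out = filter_unexpressed(out, params)
    out = filter_most_variable(out, params)
    if reference_sample_ids == "auto":
        normals = out.samples_of_class("normal")
        reference_sample_ids = normals if normals else None
    return center_to_reference(out, reference_sample_ids)
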