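"""Functional genomic mRNA profiling: transcriptional-component correction.

Most expression variance in a cohort reflects transcriptional programmes,
not DNA copy number.  Fitting the dominant principal axes of a non-cancer
reference compendium and projecting them out of each cancer sample leaves a
residual profile that tracks copy number much more closely.  The default of
25 components follows common practice for large reference compendia; the
right k depends on the reference, so it is configurable.

The module also provides the autocorrelation instability score: with genes
in genomic order, copy-number events create runs of co-shifted neighbours,
so the lag-10 autocorrelation of a sample's profile rises with its
aberration burden.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort

__all__ = [
    "TranscriptionalComponents", "AutocorrelationParams", "fit_components",
    "correct_profiles", "autocorrelation_dgi", "autocorrelation_table",
]


@dataclass
class TranscriptionalComponents:
    """Top-k principal axes (gene space) of a reference compendium.

    ``loadings`` is gene × k with mutually orthogonal unit-norm columns,
    ordered by explained variance, descending.
    """
    loadings: np.ndarray
    gene_ids: list[str]
    explained_variance: np.ndarray
    training_samples: int

    @property
    def k(self) -> int:
        return 0 if self.loadings is None else self.loadings.shape[1]

    def save(self, path, sidecar_path=None) -> None:
        df = pd.DataFrame(self.loadings, columns=[f"pc{i+1}" for i in range(self.k)])
        df.insert(0, "gene_id", self.gene_ids)
        df.to_csv(path, sep="\t", index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump({"k": self.k, "training_samples": self.training_samples,
                           "explained_variance": list(map(float, self.explained_variance))},
                          fh, indent=1)

    @classmethod
    def load(cls, path, sidecar_path=None) -> "TranscriptionalComponents":
        df = pd.read_csv(path, sep="\t")
        pcs = [c for c in df.columns if c.startswith("pc")]
        training = 0
        ev = np.zeros(len(pcs))
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta = json.load(fh)
            training = int(meta.get("training_samples", 0))
            ev = np.asarray(meta.get("explained_variance", ev), float)
        return cls(loadings=df[pcs].values, gene_ids=list(df["gene_id"].astype(str)),
                   explained_variance=ev, training_samples=training)


@dataclass
class AutocorrelationParams:
    lag: int = 10

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


def fit_components(reference: ExpressionCohort, k: int) -> TranscriptionalComponents:
    """Principal axes of the gene-centred reference compendium.

    Genes are centred (not scaled — scaling would distort dosage effects)
    before the SVD; requires more reference samples than components.
    """
    n = reference.n_samples
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= n:
        raise ValueError(f"k={k} requires more than {k} reference samples (have {n})")
    gene_ids = list(reference.genes["gene_id"].astype(str))
    if k == 0:
        return TranscriptionalComponents(
            loadings=np.zeros((len(gene_ids), 0)), gene_ids=gene_ids,
            explained_variance=np.zeros(0), training_samples=n)
    X = reference.values.values
    Xc = X - X.mean(axis=1, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    ev = (S ** 2) / max(n - 1, 1)
    return TranscriptionalComponents(loadings=U[:, :k], gene_ids=gene_ids,
                                     explained_variance=ev[:k],
                                     training_samples=n)


def correct_profiles(cohort: ExpressionCohort,
                     components: TranscriptionalComponents,
                     min_overlap: float = 0.5) -> ExpressionCohort:
    """Residualize each sample against the transcriptional components.

    The matrix is restricted to genes shared with the component training
    set (an error below ``min_overlap`` overlap), and each sample vector is
    replaced by its residual after orthogonal projection onto the span of
    the loadings.  Idempotent; residuals are orthogonal to every loading.
    """
    if components.k == 0:
        return cohort
    gene_ids = list(cohort.genes["gene_id"].astype(str))
    comp_index = {g: i for i, g in enumerate(components.gene_ids)}
    shared = [g for g in gene_ids if g in comp_index]
    if len(shared) < min_overlap * len(gene_ids):
        raise ValueError(
            f"only {len(shared)}/{len(gene_ids)} genes shared with the "
            f"component set; need >= {min_overlap:.0%} to project meaningfully")
    keep = np.array([g in comp_index for g in gene_ids])
    sub = cohort.with_genes(keep)
    L = components.loadings[[comp_index[g] for g in shared], :]
    # Re-orthonormalize after subsetting: the rows kept need not preserve
    # the original orthogonality of the loading columns.
    Q, _ = np.linalg.qr(L)
    X = sub.values.values
    resid = X - Q @ (Q.T @ X)
    return replace(sub, values=pd.DataFrame(resid, index=sub.values.index,
                                            columns=sub.values.columns))


def autocorrelation_dgi(values, chromosomes,
                        params: AutocorrelationParams | None = None) -> float:
    """Lag autocorrelation of one genome-ordered sample profile.

    Pearson correlation between the vector and its lag-shifted copy,
    computed within chromosomes (lag pairs never straddle a chromosome
    boundary) and combined by a length-weighted average.  Zero-variance
    input yields 0 with a warning (no signal to correlate).
    """
    params = params or AutocorrelationParams()
    x = np.asarray(values, dtype=float)
    chrom = np.asarray(chromosomes)
    if x.size != chrom.size:
        raise ValueError("values and chromosomes lengths differ")
    if x.size <= params.lag:
        raise ValueError("vector shorter than the lag")
    if np.ptp(x) == 0:
        warnings.warn("zero-variance profile: autocorrelation undefined, returning 0")
        return 0.0
    num, den = 0.0, 0.0
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            seg = x[start:i]
            m = seg.size - params.lag
            if m >= 2:
                a, b = seg[:-params.lag], seg[params.lag:]
                if np.ptp(a) > 0 and np.ptp(b) > 0:
                    r = np.corrcoef(a, b)[0, 1]
                    num += seg.size * r
                    den += seg.size
            start = i
    if den == 0:
        warnings.warn("no chromosome long enough for the requested lag; returning 0")
        return 0.0
    return float(num / den)


def autocorrelation_table(cohort: ExpressionCohort,
                          params: AutocorrelationParams | None = None) -> pd.DataFrame:
    """Per-sample autocorrelation instability scores for a cohort."""
    chrom = cohort.genes["chromosome"].values
    rows = [{"sample": s,
             "autocorr_dgi": autocorrelation_dgi(cohort.values[s].values, chrom,
                                                 params)}
            for s in cohort.values.columns]
    return pd.DataFrame(rows, columns=["sample", "autocorr_dgi"])
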