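"""Per-sample genomic-instability measures and group-comparison statistics.

Three degree-of-genomic-instability (DGI) readouts are supported:

* aberration count — discrete called aberrations per sample (adjacent
  same-sign called segments merged);
* altered-gene fraction — genes inside called segments over all genes;
* lag autocorrelation — see :mod:`ekaryo.fgmp`.

Group comparisons follow the conventions used for cohort contrasts of this
kind: χ² test of independence for prevalence tables (Fisher's exact test
when any condition has fewer than 10 samples), Mann–Whitney U for two-group
score comparisons, Kruskal–Wallis plus Dunn's post-hoc (Bonferroni) for
multi-group ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import SegmentSet, classify_sample

__all__ = [
    "DGIRecord", "GroupComparison", "dgi_table", "prevalence",
    "compare_prevalence", "compare_dgi_distributions", "dunn_posthoc",
    "binomial_fdr_bound",
]


@dataclass
class DGIRecord:
    sample_id: str
    n_aberrations: int
    altered_gene_fraction: float
    autocorr_dgi: float | None = None
    classification: str = "diploid"


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    groups: list
    sizes: list
    table: object = None
    posthoc: pd.DataFrame | None = None


def dgi_table(segset: SegmentSet, total_genes: int | None = None,
              autocorr: pd.DataFrame | None = None) -> pd.DataFrame:
    """One DGI record per sample from a called segment set.

    ``altered_gene_fraction`` counts genes inside non-zero-called segments
    over ``total_genes`` (defaults to the segment set's own gene total).
    Optionally merges a per-sample ``autocorr_dgi`` table.
    """
    total = total_genes if total_genes is not None else segset.total_genes
    if not total:
        raise ValueError("total_genes must be > 0")
    rows = []
    for sample, grp in segset.segments.groupby("sample", sort=False):
        label, count = classify_sample(grp)
        altered = int(grp.loc[grp["call"] != 0, "n_genes"].sum())
        rows.append({"sample": sample, "n_aberrations": count,
                     "altered_gene_fraction": altered / total,
                     "classification": {"diploid": "diploid",
                                        "single_CNA": "single",
                                        "multiple_CNA": "multiple"}[label]})
    out = pd.DataFrame(rows, columns=["sample", "n_aberrations",
                                      "altered_gene_fraction", "classification"])
    if autocorr is not None:
        out = out.merge(autocorr, on="sample", how="left")
    return out


def prevalence(records: pd.DataFrame, group_mask=None) -> tuple[int, int, float]:
    """(k aberrant, n total, fraction) where aberrant means ≥1 aberration."""
    sub = records if group_mask is None else records[group_mask]
    if len(sub) == 0:
        raise ValueError("empty group")
    k = int((sub["n_aberrations"] >= 1).sum())
    return k, len(sub), k / len(sub)


def compare_prevalence(groups: dict[str, tuple[int, int]],
                       yates: bool = False) -> GroupComparison:
    """Test whether CNA prevalence differs between groups.

    ``groups`` maps group name → (k aberrant, n total).  Builds the
    aberrant/non-aberrant contingency table; uses Fisher's exact test when
    any group total is below 10 (only defined for two groups), else the
    χ² test of independence (no continuity correction unless ``yates``).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    table = np.array([[groups[g][0], groups[g][1] - groups[g][0]] for g in names])
    if (table < 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    sizes = [int(groups[g][1]) for g in names]
    use_fisher = any(n < 10 for n in sizes) and len(names) == 2
    if use_fisher:
        stat, p = stats.fisher_exact(table)
        name = "fisher_exact"
    else:
        if (table.sum(axis=0) == 0).any():
            raise ValueError("degenerate contingency table (empty margin)")
        stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
        name = "chi2_independence"
    return GroupComparison(test_name=name, statistic=float(stat),
                           p_value=float(p), groups=names, sizes=sizes,
                           table=table)


def compare_dgi_distributions(groups: dict[str, np.ndarray],
                              mode: str = "auto") -> GroupComparison:
    """Compare a DGI score between groups.

    Two groups → Mann–Whitney U (two-sided); more → Kruskal–Wallis with an
    all-pairs Dunn post-hoc (Bonferroni-adjusted) attached.
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    if any(len(d) < 2 for d in data):
        raise ValueError("each group needs at least 2 observations")
    if mode == "auto":
        mode = "two_group" if len(names) == 2 else "multi_group"
    if mode == "two_group":
        if len(names) != 2:
            raise ValueError("two_group mode needs exactly two groups")
        res = stats.mannwhitneyu(data[0], data[1], alternative="two-sided")
        return GroupComparison("mann_whitney", float(res.statistic),
                               float(res.pvalue), names,
                               [len(d) for d in data])
    res = stats.kruskal(*data)
    posthoc = dunn_posthoc(dict(zip(names, data)))
    return GroupComparison("kruskal_wallis", float(res.statistic),
                           float(res.pvalue), names, [len(d) for d in data],
                           posthoc=posthoc)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Dunn's test on pooled ranks, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j)) with the
    standard tie correction T = Σ(t³−t) / (12(N−1)).
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    pooled = np.concatenate(data)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for d in data:
        mean_ranks.append(ranks[start:start + len(d)].mean())
        sizes.append(len(d))
        start += len(d)
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": names[i], "group_b": names[j],
                         "z": z, "p_value": p,
                         "p_adjusted": min(1.0, p * m)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_value",
                                       "p_adjusted"])


def binomial_fdr_bound(k_false: int, n: int, confidence: float = 0.95) -> float:
    """Exact (Clopper–Pearson) one-sided upper confidence bound for the
    per-sample false-call probability given ``k_false`` false calls in
    ``n`` samples.  For k=0 this is 1 − (1−confidence)^(1/n)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k_false <= n:
        raise ValueError("need 0 <= k_false <= n")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    if k_false == n:
        return 1.0
    return float(stats.beta.ppf(confidence, k_false + 1, n - k_false))
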