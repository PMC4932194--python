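"""Piecewise-constant-fit detection of regional expression biases.

Each sample's comparative (reference-centred) expression vector is, per
chromosome, winsorized and segmented by an exact penalized least-squares
piecewise constant fit (PCF):

    minimize  Σ_segments Σ_i (x_i − mean_seg)²  +  penalty · γ · #breakpoints

solved exactly by dynamic programming.  γ is a robust per-vector noise
variance estimate, (median |successive difference| / (√2·0.6745))², so the
dimensionless penalty (default 14, published working range 12–18) keeps its
meaning across noise levels.  A segment becomes a called gain (+1) or loss
(−1) when its |mean| reaches ``least_allowed_deviation`` (default 0.25,
range 0.15–0.4), it spans at least ``least_allowed_aberration_size`` genes
(default 50, range 50–80), and — when the significance check is enabled —
its mean is distinguishable from 0 at level ``threshold`` (default 0.01).

Gene indices are 0-based inclusive internally; bp output is 1-based
inclusive, matching the SEG convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionCohort

__all__ = [
    "PCFParams", "SegmentSet", "winsorize", "robust_noise_variance",
    "pcf_segment", "pcf_objective", "call_segments", "segment_cohort",
    "moving_average_profile", "classify_sample", "classify_samples",
    "export_seg", "read_seg",
]


@dataclass
class PCFParams:
    least_allowed_deviation: float = 0.25
    least_allowed_aberration_size: int = 50
    winsorize_quantile: float = 0.001
    penalty: float = 14.0
    threshold: float | None = 0.01   # None disables the mean-vs-0 check

    def __post_init__(self):
        if self.least_allowed_deviation <= 0:
            raise ValueError("least_allowed_deviation must be > 0")
        if self.least_allowed_aberration_size < 2:
            raise ValueError("least_allowed_aberration_size must be >= 2")
        if not 0.0 < self.winsorize_quantile < 0.5:
            raise ValueError("winsorize_quantile must lie in (0, 0.5)")
        if self.penalty <= 0:
            raise ValueError("penalty must be > 0")


@dataclass
class SegmentSet:
    """All segments of a cohort plus the parameters that produced them.

    ``segments`` columns: sample, chromosome, start_idx, end_idx (0-based
    inclusive gene indices within the chromosome), n_genes, start_bp,
    end_bp (1-based inclusive), mean_dev, p_mean, call.
    """
    segments: pd.DataFrame
    params: PCFParams = field(default_factory=PCFParams)
    total_genes: int = 0

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.segments[self.segments["sample"] == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.segments["sample"]))


# ---------------------------------------------------------------------------

def winsorize(values, quantile: float) -> np.ndarray:
    """Clamp values outside the q-th / (1−q)-th empirical quantiles."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not 0.0 < quantile < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    # 'nearest' keeps the clamp on observed values and is reflection-
    # symmetric (winsorizing -x mirrors winsorizing x)
    lo = np.quantile(x, quantile, method="nearest")
    hi = np.quantile(x, 1.0 - quantile, method="nearest")
    return np.clip(x, lo, hi)


def robust_noise_variance(values) -> float:
    """γ = (median |successive difference| / (√2·0.6745))² — a variance
    estimate immune to step changes, which affect few differences."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    mad = float(np.median(np.abs(np.diff(x))))
    return (mad / (np.sqrt(2.0) * 0.6745)) ** 2


def pcf_segment(values, params: PCFParams | None = None,
                penalty_lam: float | None = None) -> list[tuple[int, int, float]]:
    """Exact optimal PCF of one ordered vector.

    Returns ``[(start, end, mean), ...]`` with 0-based inclusive indices
    forming an exhaustive partition.  The breakpoint cost is
    ``penalty_lam`` when given, else ``params.penalty · γ(values)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    if penalty_lam is None:
        params = params or PCFParams()
        penalty_lam = params.penalty * max(robust_noise_variance(x), 1e-12)
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    # D[i] = optimal cost of x[:i] including one lam per segment; subtracting
    # lam at the end converts segment count to breakpoint count.
    D = np.empty(n + 1)
    D[0] = 0.0
    back = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, n + 1):
        lens = np.arange(i, 0, -1, dtype=float)
        sse = (cs2[i] - cs2[:i]) - (cs[i] - cs[:i]) ** 2 / lens
        tot = D[:i] + sse + penalty_lam
        j = int(np.argmin(tot))
        D[i] = tot[j]
        back[i] = j
    cuts = []
    i = n
    while i > 0:
        j = back[i]
        cuts.append((j, i))
        i = j
    cuts.reverse()
    return [(s, e - 1, float((cs[e] - cs[s]) / (e - s))) for s, e in cuts]


def pcf_objective(x, segments, penalty_lam: float) -> float:
    """SSE + penalty_lam · breakpoints for a given partition (oracle hook)."""
    x = np.asarray(x, dtype=float)
    sse = 0.0
    for s, e, *_ in segments:
        seg = x[s:e + 1]
        sse += float(np.sum((seg - seg.mean()) ** 2))
    return sse + penalty_lam * (len(segments) - 1)


# ---------------------------------------------------------------------------

def _segment_call(mean: float, n_genes: int, p_mean: float,
                  params: PCFParams) -> int:
    if n_genes < params.least_allowed_aberration_size:
        return 0
    if abs(mean) < params.least_allowed_deviation:
        return 0
    if params.threshold is not None and p_mean >= params.threshold:
        return 0
    return -1 if mean < 0 else 1


def call_segments(segments: pd.DataFrame, params: PCFParams,
                  total_genes: int = 0) -> SegmentSet:
    """Assign ternary calls: ±1 when |mean| and size pass their thresholds
    (and the mean-vs-0 check when enabled), else 0."""
    seg = segments.copy()
    if "p_mean" not in seg.columns:
        seg["p_mean"] = 0.0
    seg["call"] = [
        _segment_call(m, n, p, params)
        for m, n, p in zip(seg["mean_dev"], seg["n_genes"], seg["p_mean"])
    ]
    return SegmentSet(segments=seg, params=params, total_genes=total_genes)


def _mean_vs_zero_p(seg_values: np.ndarray) -> float:
    """One-sample t-test p of the segment mean against 0; degenerate
    zero-variance segments count as significant iff their value is non-zero."""
    if seg_values.size < 2 or np.ptp(seg_values) == 0:
        return 0.0 if seg_values.size and seg_values[0] != 0 else 1.0
    t = stats.ttest_1samp(seg_values, 0.0)
    return float(t.pvalue)


def segment_cohort(cohort: ExpressionCohort,
                   params: PCFParams | None = None) -> SegmentSet:
    """Winsorize + PCF + call every sample of a comparative matrix.

    Segment means are computed on the winsorized values; bp coordinates are
    taken from the first/last gene of each segment (1-based inclusive).
    """
    params = params or PCFParams()
    genes = cohort.genes
    rows = []
    chrom_groups = [(chrom, np.flatnonzero((genes["chromosome"] == chrom).values))
                    for chrom in dict.fromkeys(genes["chromosome"])]
    values = cohort.values.values
    positions = genes["position"].values
    for sample in cohort.values.columns:
        si = cohort.values.columns.get_loc(sample)
        for chrom, idx in chrom_groups:
            x = values[idx, si]
            w = winsorize(x, params.winsorize_quantile)
            for s, e, mean in pcf_segment(w, params):
                seg_vals = w[s:e + 1]
                rows.append({
                    "sample": sample, "chromosome": str(chrom),
                    "start_idx": s, "end_idx": e, "n_genes": e - s + 1,
                    "start_bp": int(positions[idx[s]]),
                    "end_bp": int(positions[idx[e]]),
                    "mean_dev": mean,
                    "p_mean": _mean_vs_zero_p(seg_vals),
                })
    seg = pd.DataFrame(rows, columns=["sample", "chromosome", "start_idx",
                                      "end_idx", "n_genes", "start_bp",
                                      "end_bp", "mean_dev", "p_mean"])
    return call_segments(seg, params, total_genes=cohort.n_genes)


# ---------------------------------------------------------------------------

def moving_average_profile(values, window: int = 200) -> np.ndarray:
    """Centred moving mean with a symmetrically shrinking window at the ends.

    At index i the mean is taken over [i−k, i+k] with
    k = min(window // 2, i, n−1−i); ``window=1`` is the identity.
    Apply per chromosome.
    """
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = x.size
    if n == 0:
        return x.copy()
    h = window // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    k = np.minimum(h, np.minimum(i, n - 1 - i))
    return (cs[i + k + 1] - cs[i - k]) / (2 * k + 1)


def classify_sample(calls: pd.DataFrame) -> tuple[str, int]:
    """Classification of one sample from its per-chromosome segment calls.

    Adjacent called segments of the same sign merge into one aberration;
    the count of such runs over all chromosomes yields
    diploid (0) / single_CNA (1) / multiple_CNA (>1).
    """
    count = 0
    for _, grp in calls.groupby("chromosome", sort=False):
        c = grp.sort_values("start_idx")["call"].values
        prev = 0
        for v in c:
            if v != 0 and v != prev:
                count += 1
            prev = v
    label = "diploid" if count == 0 else ("single_CNA" if count == 1 else "multiple_CNA")
    return label, count


def classify_samples(segset: SegmentSet) -> pd.DataFrame:
    """Per-sample aberration counts and diploid/single/multiple labels."""
    rows = []
    for sample, grp in segset.segments.groupby("sample", sort=False):
        label, count = classify_sample(grp)
        rows.append({"sample": sample, "n_aberrations": count,
                     "classification": label})
    return pd.DataFrame(rows, columns=["sample", "n_aberrations", "classification"])


# ---------------------------------------------------------------------------
# SEG I/O (IGV dialect)

_SEG_COLS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Seg_Mean",
             "Call"]


def export_seg(segset: SegmentSet, path,
               valid_chromosomes: list[str] | None = None) -> None:
    """Write the segment list as a tab-separated IGV-style SEG file."""
    seg = segset.segments
    if valid_chromosomes is not None:
        bad = sorted(set(seg["chromosome"].astype(str))
                     - set(str(c) for c in valid_chromosomes))
        if bad:
            raise ValueError(f"unknown chromosome name(s): {bad}")
    out = pd.DataFrame({
        "Sample": seg["sample"],
        "Chromosome": seg["chromosome"],
        "Start": seg["start_bp"].astype(int),
        "End": seg["end_bp"].astype(int),
        "Num_Probes": seg["n_genes"].astype(int),
        "Seg_Mean": seg["mean_dev"],
        "Call": seg["call"].astype(int),
    }, columns=_SEG_COLS)
    out.to_csv(path, sep="\t", index=False)


def read_seg(path, params: PCFParams | None = None) -> SegmentSet:
    """Read a SEG file written by :func:`export_seg` (Call column optional)."""
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in _SEG_COLS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file lacks columns: {missing}")
    seg = pd.DataFrame({
        "sample": df["Sample"].astype(str),
        "chromosome": df["Chromosome"].astype(str),
        "start_idx": -1, "end_idx": -1,
        "n_genes": df["Num_Probes"].astype(int),
        "start_bp": df["Start"].astype(int),
        "end_bp": df["End"].astype(int),
        "mean_dev": df["Seg_Mean"].astype(float),
        "p_mean": 0.0,
        "call": df["Call"].astype(int) if "Call" in df.columns else 0,
    })
    return SegmentSet(segments=seg, params=params or PCFParams())
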