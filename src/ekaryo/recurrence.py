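"""Cytoband recurrence statistics and arm-level calling from DNA segments.

Segment calls are projected onto cytobands to give a bands × samples
ternary matrix (−1 loss, 0 neutral, +1 gain).  Within one model a band is
*recurrent* in a direction if its event prevalence exceeds 10% of the N
samples, or if a one-sided binomial test against the pooled background rate
is significant after Bonferroni correction.  The background probability
p_c for band c is the direction's event frequency over all *other* bands:
p_c = (events elsewhere) / (N · (n_bands − 1)); gains and losses are tested
(and Bonferroni-corrected) separately.  Model specificity of a (band,
direction) event is a χ² test of independence on the models × event/no-event
table, Bonferroni-corrected over all pairs tested.

For segmented DNA copy-number input, log2 ratios are median-centred per
sample, converted to relative copies (r → 2·2^r − 2, capped at ±1.5), and
an arm is called ±1 when its length-weighted median relative copy number
exceeds ±0.1 (strict), else 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import normalize_chromosome
from .segmentation import SegmentSet

__all__ = [
    "CytobandCallMatrix", "segments_to_cytobands", "recurrence_test",
    "specificity_test", "specificity_scan", "frequency_profile",
    "log2ratio_to_relative_copy", "arm_level_calls", "arm_burden",
]


@dataclass
class CytobandCallMatrix:
    """Cytobands × samples ternary calls plus band and sample metadata."""
    calls: pd.DataFrame            # index = cytoband, columns = samples
    bands: pd.DataFrame            # cytoband, chromosome, start, end, arm
    model_labels: pd.Series        # sample -> model label

    def __post_init__(self):
        vals = self.calls.values
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("cytoband calls must be in {-1, 0, +1}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def restrict_model(self, model: str) -> "CytobandCallMatrix":
        keep = self.model_labels[self.model_labels == model].index
        if len(keep) == 0:
            raise ValueError(f"no samples for model {model!r}")
        return CytobandCallMatrix(self.calls[list(keep)], self.bands,
                                  self.model_labels[keep])

    def to_tsv(self, path) -> None:
        out = self.bands[["cytoband", "chromosome", "start", "end", "arm"]].copy()
        out = out.merge(self.calls.reset_index(), on="cytoband")
        out.to_csv(path, sep="\t", index=False)


def segments_to_cytobands(segset: SegmentSet, bands: pd.DataFrame,
                          model_labels: pd.Series | None = None) -> CytobandCallMatrix:
    """Assign each cytoband the call of the segment(s) overlapping it.

    When segments with different calls overlap one band, the call covering
    the largest fraction of the band wins; ties resolve to 0.  Bands must
    not overlap within a chromosome.
    """
    bands = bands.copy()
    bands["chromosome"] = bands["chromosome"].map(normalize_chromosome)
    for chrom, grp in bands.groupby("chromosome"):
        g = grp.sort_values("start")
        if (g["start"].values[1:] < g["end"].values[:-1]).any():
            raise ValueError(f"overlapping cytobands on chromosome {chrom}")
    seg = segset.segments.copy()
    seg["chromosome"] = seg["chromosome"].map(normalize_chromosome)
    samples = list(dict.fromkeys(seg["sample"]))
    calls = pd.DataFrame(0, index=bands["cytoband"], columns=samples, dtype=int)
    for sample, sgrp in seg.groupby("sample", sort=False):
        for _, band in bands.iterrows():
            bs, be = band["start"], band["end"]
            blen = be - bs
            on = sgrp[sgrp["chromosome"] == band["chromosome"]]
            cover = {-1: 0.0, 0: 0.0, 1: 0.0}
            for _, s in on.iterrows():
                # segments carry 1-based inclusive bp; bands half-open 0-based
                ov = min(be, s["end_bp"]) - max(bs, s["start_bp"] - 1)
                if ov > 0:
                    cover[int(s["call"])] += ov / blen
            best = max(cover.values())
            winners = [c for c, v in cover.items() if v == best and v > 0]
            calls.loc[band["cytoband"], sample] = winners[0] if len(winners) == 1 else 0
    if model_labels is None:
        model_labels = pd.Series("model", index=samples)
    return CytobandCallMatrix(calls=calls, bands=bands,
                              model_labels=model_labels.loc[samples])


# ---------------------------------------------------------------------------
# recurrence

_DIR_SIGN = {"gain": 1, "loss": -1}


def recurrence_test(matrix: CytobandCallMatrix, direction: str,
                    prevalence_cutoff: float = 0.10,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-cytoband recurrence of one direction within one model.

    Returns a table with K_c, N, frequency, the pooled background p_c, the
    one-sided binomial tail P[Bin(N, p_c) ≥ K_c], its Bonferroni adjustment
    (multiplier = bands tested in this direction), and the two recurrence
    flags (prevalence > 10%; adjusted p < 0.05).
    """
    sign = _DIR_SIGN[direction]
    calls = matrix.calls.values
    n_bands, N = calls.shape
    if n_bands < 2:
        raise ValueError("need at least 2 cytobands")
    hits = (calls == sign).sum(axis=1)
    total = int(hits.sum())
    rows = []
    for ci, band in enumerate(matrix.calls.index):
        K = int(hits[ci])
        p_c = (total - K) / (N * (n_bands - 1))
        if p_c == 0.0:
            p_binom = 0.0 if K > 0 else 1.0
            degenerate = K > 0
        else:
            p_binom = float(stats.binom.sf(K - 1, N, p_c)) if K > 0 else 1.0
            degenerate = False
        p_bonf = min(1.0, p_binom * n_bands)
        freq = K / N
        rows.append({
            "cytoband": band, "direction": direction, "K": K, "N": N,
            "frequency": freq, "p_background": p_c, "p_binomial": p_binom,
            "p_bonferroni": p_bonf,
            "recurrent_by_prevalence": freq > prevalence_cutoff,
            "recurrent_by_test": p_bonf < alpha,
            "zero_background": degenerate,
        })
    out = pd.DataFrame(rows)
    out["recurrent"] = out["recurrent_by_prevalence"] | out["recurrent_by_test"]
    return out


def specificity_test(matrix: CytobandCallMatrix, cytoband: str, direction: str,
                     n_tests: int = 1, alpha: float = 0.05) -> dict:
    """χ² independence of one (band, direction) event across models.

    ``n_tests`` is the Bonferroni family size (all pairs tested in a scan).
    The event is attributed to the model with the highest frequency.
    """
    sign = _DIR_SIGN[direction]
    models = sorted(matrix.model_labels.unique())
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    row = matrix.calls.loc[cytoband]
    counts, sizes = [], []
    for m in models:
        cols = matrix.model_labels[matrix.model_labels == m].index
        vals = row[list(cols)].values
        counts.append(int((vals == sign).sum()))
        sizes.append(len(cols))
    table = np.array([[k, n - k] for k, n in zip(counts, sizes)])
    result = {"cytoband": cytoband, "direction": direction,
              "models": models, "event_counts": counts, "sizes": sizes}
    if table[:, 0].sum() == 0:
        result.update({"chi2": np.nan, "p_value": np.nan,
                       "p_bonferroni": np.nan, "model_specific": False,
                       "testable": False, "attributed_model": None})
        return result
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    p_bonf = min(1.0, p * n_tests)
    freqs = [k / n for k, n in zip(counts, sizes)]
    result.update({"chi2": float(chi2), "p_value": float(p),
                   "p_bonferroni": float(p_bonf),
                   "model_specific": p_bonf < alpha, "testable": True,
                   "attributed_model": models[int(np.argmax(freqs))]})
    return result


def specificity_scan(matrix: CytobandCallMatrix, alpha: float = 0.05,
                     min_events: int = 1) -> pd.DataFrame:
    """All (band, direction) specificity tests, Bonferroni over the family
    of testable pairs (those with at least ``min_events`` events)."""
    pairs = []
    for direction in ("gain", "loss"):
        sign = _DIR_SIGN[direction]
        ev = (matrix.calls.values == sign).sum(axis=1)
        for band, k in zip(matrix.calls.index, ev):
            if k >= min_events:
                pairs.append((band, direction))
    rows = [specificity_test(matrix, band, direction, n_tests=len(pairs),
                             alpha=alpha)
            for band, direction in pairs]
    return pd.DataFrame(rows)


def frequency_profile(matrix: CytobandCallMatrix,
                      model: str | None = None) -> pd.DataFrame:
    """Per-band gain and loss frequencies (independent of each other)."""
    m = matrix if model is None else matrix.restrict_model(model)
    calls = m.calls.values
    return pd.DataFrame({
        "cytoband": m.calls.index,
        "gain_frequency": (calls == 1).mean(axis=1),
        "loss_frequency": (calls == -1).mean(axis=1),
    })


# ---------------------------------------------------------------------------
# arm-level calling from segmented DNA copy number

def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    half = 0.5 * cw[-1]
    i = int(np.searchsorted(cw, half))
    if cw[i] == half and i + 1 < len(v):
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])


def log2ratio_to_relative_copy(segments: pd.DataFrame,
                               cap: float = 1.5) -> pd.DataFrame:
    """Median-centre per sample and convert log2 ratios to relative copies.

    The sample's length-weighted median log2 ratio is subtracted, then
    r → 2·2^r − 2 (copies gained/lost relative to diploid), clamped to
    ±``cap``.  Expects columns sample, chromosome, start, end, value.
    """
    if not np.isfinite(segments["value"]).all():
        raise ValueError("non-finite log2 ratios")
    out = segments.copy()
    for sample, grp in out.groupby("sample", sort=False):
        lengths = (grp["end"] - grp["start"] + 1).values.astype(float)
        med = _weighted_median(grp["value"].values.astype(float), lengths)
        r = grp["value"].values - med
        rel = 2.0 * np.power(2.0, r) - 2.0
        out.loc[grp.index, "value"] = np.clip(rel, -cap, cap)
    return out


def arm_level_calls(segments: pd.DataFrame, arms: pd.DataFrame,
                    threshold: float = 0.1,
                    min_covered_fraction: float = 0.5) -> pd.DataFrame:
    """Ternary arm calls from relative-copy segments.

    The arm median is the length-weighted median of segment values
    intersected with the arm; values strictly above +threshold call +1,
    strictly below −threshold call −1, else 0 (an exact ±threshold median
    is 0).  Arms with less than ``min_covered_fraction`` of their length
    covered are reported as missing (NaN call, excluded from burdens).

    Returns a tidy frame: sample, chromosome, arm, arm_median, call.
    """
    seg = segments.copy()
    seg["chromosome"] = seg["chromosome"].map(normalize_chromosome)
    arms = arms.copy()
    arms["chromosome"] = arms["chromosome"].map(normalize_chromosome)
    rows = []
    for sample, grp in seg.groupby("sample", sort=False):
        for _, arm in arms.iterrows():
            a_s, a_e = int(arm["start"]), int(arm["end"])
            on = grp[grp["chromosome"] == arm["chromosome"]]
            # segments are 1-based inclusive; arms half-open 0-based
            ov_start = np.maximum(on["start"].values - 1, a_s)
            ov_end = np.minimum(on["end"].values, a_e)
            lengths = (ov_end - ov_start).astype(float)
            keep = lengths > 0
            arm_len = a_e - a_s
            if lengths[keep].sum() < min_covered_fraction * arm_len:
                rows.append({"sample": sample, "chromosome": arm["chromosome"],
                             "arm": arm["arm"], "arm_median": np.nan,
                             "call": np.nan})
                continue
            med = _weighted_median(on["value"].values[keep].astype(float),
                                   lengths[keep])
            call = 1 if med > threshold else (-1 if med < -threshold else 0)
            rows.append({"sample": sample, "chromosome": arm["chromosome"],
                         "arm": arm["arm"], "arm_median": med, "call": call})
    return pd.DataFrame(rows, columns=["sample", "chromosome", "arm",
                                       "arm_median", "call"])


def arm_burden(arm_calls: pd.DataFrame) -> pd.Series:
    """Per-sample count of non-zero (and non-missing) arm calls."""
    nz = arm_calls.dropna(subset=["call"])
    nz = nz[nz["call"] != 0]
    counts = nz.groupby("sample").size()
    all_samples = arm_calls["sample"].unique()
    return counts.reindex(all_samples, fill_value=0).astype(int)
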