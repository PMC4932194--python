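"""Cross-species narrowing of recurrent regions and the information coefficient.

Mouse–human (or any A–B) comparisons exploit incomplete synteny: a recurrent
region in species A maps through synteny blocks to a set of intervals in
species B; intersecting those with species-B recurrent regions yields a
smaller *critical region* in both species.  Candidate driver genes are the
orthologues inside the critical region whose differential expression in
species A is concordant with the event direction.

The information coefficient (IC) is a mutual-information-based association
measure rescaled to [−1, 1]: IC = sign(r) · sqrt(1 − exp(−2·MI)), where r is
the Pearson correlation and MI the differential mutual information estimated
by bivariate Gaussian kernel density.  For bivariate Gaussian data MI =
−½·log(1−ρ²), so IC converges to ρ — the rescaling behaves like a
correlation coefficient while remaining sensitive to non-linear dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import normalize_chromosome

__all__ = [
    "SyntenyBlock", "OrthologyPair", "NarrowingResult", "CandidateGene",
    "map_region", "back_map_region", "narrow_critical_region",
    "candidate_genes", "information_coefficient", "merge_block_gaps",
    "read_synteny_tsv", "write_synteny_tsv",
    "read_orthology_tsv", "write_orthology_tsv",
]


@dataclass(frozen=True)
class SyntenyBlock:
    """A conserved interval pair: (chrom_a, [start_a, end_a)) ↔ (chrom_b, [start_b, end_b))."""
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str = "same"   # 'same' | 'inverted'

    def __post_init__(self):
        if self.end_a <= self.start_a or self.end_b <= self.start_b:
            raise ValueError("synteny block intervals must have positive length")
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def length_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def length_b(self) -> int:
        return self.end_b - self.start_b


@dataclass(frozen=True)
class OrthologyPair:
    gene_a: str
    gene_b: str
    confidence: str = ""


# ---------------------------------------------------------------------------
# interval helpers (bp arithmetic over lists of (start, end) half-open tuples)

def _merge_intervals(intervals):
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_intervals(a, b):
    a, b = _merge_intervals(a), _merge_intervals(b)
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _total_length(intervals) -> int:
    return sum(e - s for s, e in _merge_intervals(intervals))


def merge_block_gaps(blocks: list[SyntenyBlock], max_gap: int = 1_000_000) -> list[SyntenyBlock]:
    """Fill small gaps: merge adjacent same-chromosome-pair, same-orientation
    blocks separated by less than ``max_gap`` bp on both sides."""
    by_pair: dict[tuple, list[SyntenyBlock]] = {}
    for b in blocks:
        by_pair.setdefault((b.chrom_a, b.chrom_b, b.orientation), []).append(b)
    out = []
    for key, grp in by_pair.items():
        grp = sorted(grp, key=lambda b: b.start_a)
        cur = grp[0]
        for nxt in grp[1:]:
            gap_a = nxt.start_a - cur.end_a
            if cur.orientation == "same":
                gap_b = nxt.start_b - cur.end_b
                mergeable = 0 <= gap_a < max_gap and 0 <= gap_b < max_gap
            else:
                gap_b = cur.start_b - nxt.end_b
                mergeable = 0 <= gap_a < max_gap and 0 <= gap_b < max_gap
            if mergeable:
                if cur.orientation == "same":
                    cur = SyntenyBlock(cur.chrom_a, cur.start_a, nxt.end_a,
                                       cur.chrom_b, cur.start_b, nxt.end_b, "same")
                else:
                    cur = SyntenyBlock(cur.chrom_a, cur.start_a, nxt.end_a,
                                       cur.chrom_b, nxt.start_b, cur.end_b, "inverted")
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    return sorted(out, key=lambda b: (b.chrom_a, b.start_a))


# ---------------------------------------------------------------------------
# region mapping

def map_region(region: tuple[str, int, int], blocks: list[SyntenyBlock]):
    """Map a species-A region through synteny blocks to species-B intervals.

    Returns ``(mapped, uncovered)`` where ``mapped`` is a dict
    ``{chrom_b: [(start, end), ...]}`` obtained by linear interpolation of
    the block-covered parts of the region (orientation respected), and
    ``uncovered`` lists the (start, end) parts of the A region covered by
    no block.
    """
    chrom, start, end = normalize_chromosome(region[0]), int(region[1]), int(region[2])
    if end <= start:
        raise ValueError("region must have positive length")
    known = {normalize_chromosome(b.chrom_a) for b in blocks} | \
            {normalize_chromosome(b.chrom_b) for b in blocks}
    if chrom not in known:
        raise ValueError(f"region chromosome {chrom!r} absent from synteny map")
    mapped: dict[str, list] = {}
    covered = []
    for b in blocks:
        if normalize_chromosome(b.chrom_a) != chrom:
            continue
        s = max(start, b.start_a)
        e = min(end, b.end_a)
        if e <= s:
            continue
        covered.append((s, e))
        f0 = (s - b.start_a) / b.length_a
        f1 = (e - b.start_a) / b.length_a
        if b.orientation == "same":
            bs = b.start_b + f0 * b.length_b
            be = b.start_b + f1 * b.length_b
        else:
            bs = b.end_b - f1 * b.length_b
            be = b.end_b - f0 * b.length_b
        mapped.setdefault(normalize_chromosome(b.chrom_b), []).append(
            (int(round(bs)), int(round(be))))
    mapped = {c: _merge_intervals(iv) for c, iv in mapped.items()}
    uncovered = _subtract_intervals([(start, end)], covered)
    return mapped, uncovered


def _subtract_intervals(a, b):
    b = _merge_intervals(b)
    out = []
    for s, e in _merge_intervals(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return out


def back_map_region(region_b: tuple[str, int, int], blocks: list[SyntenyBlock]):
    """Map a species-B region back to species A (the inverse of :func:`map_region`)."""
    flipped = [SyntenyBlock(b.chrom_b, b.start_b, b.end_b,
                            b.chrom_a, b.start_a, b.end_a, b.orientation)
               for b in blocks]
    return map_region(region_b, flipped)


@dataclass
class NarrowingResult:
    region_a: tuple[str, int, int]
    mapped_b: dict
    uncovered_a: list
    critical_b: dict                      # chrom_b -> intervals
    critical_back_a: dict                 # chrom_a -> intervals
    reduction_a: float                    # % of A region excluded
    reduction_b: float                    # % of B recurrent region excluded
    direction: str = ""


def narrow_critical_region(region_a, blocks, human_recurrent: dict,
                           direction: str = "") -> NarrowingResult:
    """Intersect the synteny-mapped image of ``region_a`` with species-B
    recurrent intervals of the same direction.

    ``human_recurrent`` maps chromosome → list of (start, end) intervals.
    ``reduction_b`` is the percentage of the species-B recurrent region
    excluded by the intersection; ``reduction_a`` the percentage of the
    species-A query region excluded after back-mapping the critical region.
    """
    mapped, uncovered = map_region(region_a, blocks)
    recurrent = {normalize_chromosome(c): _merge_intervals(iv)
                 for c, iv in human_recurrent.items()}
    critical = {}
    for c, iv in mapped.items():
        inter = _intersect_intervals(iv, recurrent.get(c, []))
        if inter:
            critical[c] = inter
    rec_len = sum(_total_length(iv) for iv in recurrent.values())
    crit_len = sum(_total_length(iv) for iv in critical.values())
    reduction_b = 100.0 if rec_len == 0 else 100.0 * (1.0 - crit_len / rec_len)

    back: dict[str, list] = {}
    for c, ivs in critical.items():
        for s, e in ivs:
            m, _ = back_map_region((c, s, e), blocks)
            for ca, iv in m.items():
                back.setdefault(ca, []).extend(iv)
    back = {c: _merge_intervals(iv) for c, iv in back.items()}
    chrom_a = normalize_chromosome(region_a[0])
    region_len = int(region_a[2]) - int(region_a[1])
    in_a = _intersect_intervals(back.get(chrom_a, []),
                                [(int(region_a[1]), int(region_a[2]))])
    reduction_a = 100.0 * (1.0 - _total_length(in_a) / region_len)
    return NarrowingResult(region_a=tuple(region_a), mapped_b=mapped,
                           uncovered_a=uncovered, critical_b=critical,
                           critical_back_a=back, reduction_a=reduction_a,
                           reduction_b=reduction_b, direction=direction)


# ---------------------------------------------------------------------------
# candidate genes

@dataclass(frozen=True)
class CandidateGene:
    gene_a: str
    gene_b: str
    direction: str
    effect: float
    adjusted_p: float


def candidate_genes(critical: dict, orthology: pd.DataFrame,
                    de_table: pd.DataFrame, gene_positions_b: pd.DataFrame,
                    direction: str, alpha: float = 0.05) -> list[CandidateGene]:
    """Direction-concordant, significantly differential species-A genes whose
    orthologue lies inside the species-B critical region.

    ``de_table`` needs columns ``gene``, ``effect``, ``adjusted_p``;
    ``orthology`` needs ``gene_a``, ``gene_b``; ``gene_positions_b`` needs
    ``gene_id``, ``chromosome``, ``position``.  ``direction`` is ``gain``
    (candidates over-expressed) or ``loss`` (under-expressed).  Sorted by
    |effect| descending.
    """
    for df, cols, name in ((de_table, ("gene", "effect", "adjusted_p"), "de_table"),
                           (orthology, ("gene_a", "gene_b"), "orthology"),
                           (gene_positions_b, ("gene_id", "chromosome", "position"),
                            "gene_positions_b")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} lacks columns: {missing}")
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    if not critical:
        return []
    sign = 1.0 if direction == "gain" else -1.0
    sig = de_table[(de_table["adjusted_p"] < alpha)
                   & (np.sign(de_table["effect"]) == sign)]
    orth = orthology.merge(sig, left_on="gene_a", right_on="gene")
    pos = gene_positions_b.set_index("gene_id")
    out = []
    for _, row in orth.iterrows():
        gb = row["gene_b"]
        if gb not in pos.index:
            continue
        chrom = normalize_chromosome(pos.loc[gb, "chromosome"])
        p = float(pos.loc[gb, "position"])
        inside = any(s <= p < e for s, e in critical.get(chrom, []))
        if inside:
            out.append(CandidateGene(gene_a=row["gene_a"], gene_b=gb,
                                     direction=direction,
                                     effect=float(row["effect"]),
                                     adjusted_p=float(row["adjusted_p"])))
    return sorted(out, key=lambda g: -abs(g.effect))


# ---------------------------------------------------------------------------
# information coefficient

def _kde_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in differential mutual information from Gaussian KDEs
    (Silverman bandwidth), evaluated at the sample points."""
    kxy = stats.gaussian_kde(np.vstack([x, y]), bw_method="silverman")
    kx = stats.gaussian_kde(x, bw_method="silverman")
    ky = stats.gaussian_kde(y, bw_method="silverman")
    lj = np.log(kxy(np.vstack([x, y])))
    lm = np.log(kx(x)) + np.log(ky(y))
    return float(np.mean(lj - lm))


def information_coefficient(x, y, n_permutations: int = 0, seed: int = 0,
                            n_null: int = 5):
    """Information coefficient and (optional) permutation p-value.

    IC = sign(pearson(x, y)) · sqrt(1 − exp(−2·MI)) with MI the kernel
    plug-in differential mutual information, debiased by subtracting the
    mean plug-in MI over ``n_null`` permutations of ``y`` (the plug-in
    estimate is positively biased even under independence, which the
    rescaling would otherwise inflate).  ``p_value`` is the fraction of
    ``n_permutations`` shuffles whose |IC| reaches the observed |IC|
    (None when ``n_permutations`` is 0).  Deterministic for fixed seed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 8:
        raise ValueError("need at least 8 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    rng = np.random.default_rng(seed)

    def _ic(xv, yv, bias):
        mi = max(_kde_mutual_information(xv, yv) - bias, 0.0)
        r = np.corrcoef(xv, yv)[0, 1]
        s = 1.0 if r >= 0 else -1.0
        return s * np.sqrt(1.0 - np.exp(-2.0 * mi))

    bias = 0.0
    if n_null > 0:
        bias = float(np.mean([_kde_mutual_information(x, rng.permutation(y))
                              for _ in range(n_null)]))
    ic = _ic(x, y, bias)
    p_value = None
    if n_permutations > 0:
        null = np.array([abs(_ic(x, rng.permutation(y), bias))
                         for _ in range(n_permutations)])
        p_value = float((np.sum(null >= abs(ic)) + 1) / (n_permutations + 1))
    return float(ic), p_value


# ---------------------------------------------------------------------------
# TSV I/O

_SYNTENY_COLS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                 "orientation"]


def write_synteny_tsv(blocks: list[SyntenyBlock], path) -> None:
    pd.DataFrame([{c: getattr(b, c) for c in _SYNTENY_COLS} for b in blocks]) \
        .to_csv(path, sep="\t", index=False)


def read_synteny_tsv(path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    missing = [c for c in _SYNTENY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"synteny TSV lacks columns: {missing}")
    return [SyntenyBlock(str(r.chrom_a), int(r.start_a), int(r.end_a),
                         str(r.chrom_b), int(r.start_b), int(r.end_b),
                         str(r.orientation)) for r in df.itertuples()]


def write_orthology_tsv(pairs: list[OrthologyPair], path) -> None:
    pd.DataFrame([{"gene_a": p.gene_a, "gene_b": p.gene_b,
                   "confidence": p.confidence} for p in pairs]) \
        .to_csv(path, sep="\t", index=False)


def read_orthology_tsv(path) -> list[OrthologyPair]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("orthology TSV needs gene_a and gene_b columns")
    conf = df["confidence"] if "confidence" in df.columns else [""] * len(df)
    return [OrthologyPair(str(a), str(b), str(c) if pd.notna(c) else "")
            for a, b, c in zip(df["gene_a"], df["gene_b"], conf)]
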