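"""Synthetic genomes, cohorts and ancillary fixtures with known ground truth.

Every downstream stage of the pipeline is exercised against data whose true
chromosomal events are known exactly.  The generator emulates the
statistical structure of log-intensity expression cohorts from tumour
models: a diploid baseline, per-sample scaling effects, batch-shared
transcriptional components, additive Gaussian gene noise on the log2 scale,
detection-limit flooring, and embedded gains/losses that shift every gene
in a region by a constant log2 amount.  Model-specific aberration
prevalences span the wide range seen across tumour models (a few percent
to ~80% of samples carrying at least one large CNA).

Default effect sizes: a gain shifts expression by +0.32 log2 units (one
extra copy over a diploid background, log2(3/2)); a loss by −0.58 (a
single-copy loss attenuated from the naive −1.0 by dosage compensation).
Both are configurable — they set how detectable events are, not what the
detector does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .crossspecies import OrthologyPair, SyntenyBlock
from .genome import Genome

__all__ = [
    "CNAEvent", "CohortSpec", "GroundTruth", "SegmentedCopyNumber",
    "make_genome", "simulate_cohort", "simulate_reference_compendium",
    "simulate_dna_segments", "simulate_synteny",
    "GAIN_SHIFT", "LOSS_SHIFT",
]

GAIN_SHIFT = 0.32    # log2(3/2): one copy gained over two
LOSS_SHIFT = -0.58   # single-copy loss attenuated by dosage compensation


# ---------------------------------------------------------------------------
# genome

def make_genome(n_chromosomes: int, genes_per_chromosome: int,
                cytobands_per_chromosome: int, seed: int = 0,
                gene_spacing: int = 100_000) -> Genome:
    """Build a toy genome with evenly spaced genes and evenly sized cytobands.

    Chromosomes are named "1".."n"; each carries ``genes_per_chromosome``
    genes at ``gene_spacing`` bp intervals and ``cytobands_per_chromosome``
    bands split evenly into a p arm (first half of the bands) and a q arm.
    Deterministic for fixed arguments (the seed is kept for interface
    symmetry with the stochastic generators).
    """
    if min(n_chromosomes, genes_per_chromosome, cytobands_per_chromosome) < 1:
        raise ValueError("all counts must be >= 1")
    chrom_len = genes_per_chromosome * gene_spacing
    chroms, genes, bands = [], [], []
    for ci in range(1, n_chromosomes + 1):
        name = str(ci)
        chroms.append({"name": name, "length": chrom_len})
        nb = cytobands_per_chromosome
        edges = np.linspace(0, chrom_len, nb + 1).astype(int)
        n_p = nb // 2 if nb > 1 else 0
        for bi in range(nb):
            arm = "p" if bi < n_p else "q"
            within = bi if bi < n_p else bi - n_p
            bands.append({"cytoband": f"{name}{arm}{within + 1}",
                          "chromosome": name,
                          "start": int(edges[bi]), "end": int(edges[bi + 1]),
                          "arm": arm})
        for gi in range(genes_per_chromosome):
            pos = gi * gene_spacing + gene_spacing // 2
            genes.append({"gene_id": f"g{name}_{gi:04d}", "chromosome": name,
                          "position": pos})
    genes_df = pd.DataFrame(genes)
    bands_df = pd.DataFrame(bands)
    genome = Genome(chromosomes=pd.DataFrame(chroms), genes=genes_df.assign(
        cytoband=_assign_bands(genes_df, bands_df)), cytobands=bands_df)
    return genome


def _assign_bands(genes: pd.DataFrame, bands: pd.DataFrame) -> np.ndarray:
    out = np.empty(len(genes), dtype=object)
    for chrom, grp in genes.groupby("chromosome", sort=False):
        b = bands[bands["chromosome"] == chrom].sort_values("start")
        idx = np.searchsorted(b["end"].values, grp["position"].values, side="right")
        idx = np.clip(idx, 0, len(b) - 1)
        out[grp.index] = b["cytoband"].values[idx]
    return out


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CNAEvent:
    """One potential aberration: a region, a direction and a per-sample rate.

    ``region`` is a chromosome name ("4"), a cytoband id ("4q2"), or an
    explicit (chromosome, start_bp, end_bp) triple.  ``shift`` is the log2
    expression displacement magnitude; None selects the direction default.
    """
    region: object
    direction: str            # 'gain' | 'loss'
    probability: float
    shift: float | None = None

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.shift is not None and self.shift <= 0:
            raise ValueError("shift magnitude must be > 0")


@dataclass
class CohortSpec:
    """Recipe for one simulated cohort.

    When ``event_catalogue`` is None, each sample carries one random
    whole-chromosome event (random direction, default shift) with
    probability ``aberration_prevalence`` — the simplest process matching
    a target fraction of CNA-bearing samples.  With a catalogue, each
    event strikes each sample independently with its own probability.
    """
    n_samples: int
    model_label: str = "model"
    aberration_prevalence: float = 0.0
    event_catalogue: list[CNAEvent] | None = None
    gene_noise_sd: float = 0.2
    sample_effect_sd: float = 0.05
    baseline_mean: float = 7.0
    floor_value: float = 6.5
    n_shared_components: int = 0
    component_sd: float = 0.2
    component_loadings: np.ndarray | None = None
    tissue_class: str = "tumour"
    batch_id: str = "batch0"
    exact_prevalence: bool = False   # plant in exactly round(p·n) samples
    gain_shift: float = GAIN_SHIFT
    loss_shift: float = LOSS_SHIFT
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.aberration_prevalence <= 1.0:
            raise ValueError("aberration_prevalence must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was actually planted: per-sample aberrant regions and cohort rates."""
    sample_events: dict            # sample_id -> list of event dicts
    true_prevalence: float         # fraction of samples with >= 1 event
    band_frequency: pd.DataFrame   # cytoband, direction, frequency

    def carriers(self) -> list[str]:
        return [s for s, ev in self.sample_events.items() if ev]


def _region_gene_mask(genome: Genome, region) -> np.ndarray:
    genes = genome.genes
    if isinstance(region, (tuple, list)) and len(region) == 3:
        chrom, start, end = str(region[0]), int(region[1]), int(region[2])
        mask = ((genes["chromosome"] == chrom)
                & (genes["position"] >= start) & (genes["position"] < end))
    else:
        region = str(region)
        if (genes["chromosome"] == region).any():
            mask = genes["chromosome"] == region
        elif (genome.cytobands["cytoband"] == region).any():
            band = genome.cytobands.set_index("cytoband").loc[region]
            mask = ((genes["chromosome"] == band["chromosome"])
                    & (genes["position"] >= band["start"])
                    & (genes["position"] < band["end"]))
        else:
            raise ValueError(f"unknown region {region!r}")
    mask = mask.values
    if not mask.any():
        raise ValueError(f"region {region!r} contains no genes")
    return mask


def simulate_cohort(genome: Genome, spec: CohortSpec) -> tuple[ExpressionCohort, GroundTruth]:
    """Simulate a cohort: baseline + sample effect + shared components +
    gene noise + regional shifts, floored at the detection limit.

    Returns the expression cohort (genes in genome order) and the exact
    ground truth of the planted events.
    """
    rng = np.random.default_rng(spec.seed)
    n_genes, n = genome.n_genes, spec.n_samples
    genes = genome.genes

    values = np.full((n_genes, n), spec.baseline_mean, dtype=float)
    if spec.sample_effect_sd > 0:
        values += rng.normal(0.0, spec.sample_effect_sd, size=n)[None, :]
    if spec.n_shared_components > 0 and spec.component_sd > 0:
        if spec.component_loadings is not None:
            load = np.asarray(spec.component_loadings, float)
            if load.shape != (n_genes, spec.n_shared_components):
                raise ValueError("component_loadings shape mismatch")
        else:
            load = rng.normal(0.0, 1.0, size=(n_genes, spec.n_shared_components))
        activity = rng.normal(0.0, spec.component_sd,
                              size=(spec.n_shared_components, n))
        values += load @ activity
    if spec.gene_noise_sd > 0:
        values += rng.normal(0.0, spec.gene_noise_sd, size=(n_genes, n))

    sample_ids = [f"{spec.model_label}_s{i:03d}" for i in range(n)]
    sample_events: dict[str, list] = {s: [] for s in sample_ids}

    def _plant(si: int, mask: np.ndarray, direction: str, shift: float | None):
        mag = abs(shift) if shift is not None else (
            spec.gain_shift if direction == "gain" else abs(spec.loss_shift))
        delta = mag if direction == "gain" else -mag
        values[mask, si] += delta
        idx = np.flatnonzero(mask)
        sub = genes.iloc[idx]
        sample_events[sample_ids[si]].append({
            "chromosome": str(sub["chromosome"].iloc[0]),
            "start_bp": int(sub["position"].min()),
            "end_bp": int(sub["position"].max()),
            "direction": direction,
            "shift": delta,
            "gene_ids": list(sub["gene_id"]),
        })

    if spec.event_catalogue is None:
        if spec.exact_prevalence:
            n_carriers = int(round(spec.aberration_prevalence * n))
            carriers = np.zeros(n, dtype=bool)
            carriers[rng.choice(n, size=n_carriers, replace=False)] = True
        else:
            carriers = rng.random(n) < spec.aberration_prevalence
        chroms = list(genome.chromosomes["name"])
        for si in np.flatnonzero(carriers):
            chrom = chroms[rng.integers(len(chroms))]
            direction = "gain" if rng.random() < 0.5 else "loss"
            _plant(si, _region_gene_mask(genome, chrom), direction, None)
    else:
        masks = [(_region_gene_mask(genome, ev.region), ev)
                 for ev in spec.event_catalogue]
        for mask, ev in masks:
            hit = rng.random(n) < ev.probability
            for si in np.flatnonzero(hit):
                _plant(si, mask, ev.direction, ev.shift)

    np.maximum(values, spec.floor_value, out=values)

    vdf = pd.DataFrame(values, index=genes["gene_id"], columns=sample_ids)
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "tissue_class": spec.tissue_class,
        "model_label": spec.model_label,
        "batch_id": spec.batch_id,
    })
    cohort = ExpressionCohort(values=vdf, genes=genes.copy(), samples=samples)

    n_carriers = sum(1 for ev in sample_events.values() if ev)
    band_counts: dict[tuple, int] = {}
    for evs in sample_events.values():
        seen = set()
        for ev in evs:
            for band in set(genes.set_index("gene_id").loc[ev["gene_ids"], "cytoband"]):
                seen.add((band, ev["direction"]))
        for key in seen:
            band_counts[key] = band_counts.get(key, 0) + 1
    band_freq = pd.DataFrame(
        [{"cytoband": b, "direction": d, "frequency": c / n}
         for (b, d), c in sorted(band_counts.items())],
        columns=["cytoband", "direction", "frequency"])
    truth = GroundTruth(sample_events=sample_events,
                        true_prevalence=n_carriers / n,
                        band_frequency=band_freq)
    return cohort, truth


def simulate_reference_compendium(genome: Genome, n_samples: int,
                                  n_components: int, seed: int = 0,
                                  component_sd: float = 0.5,
                                  noise_sd: float = 0.2,
                                  baseline_mean: float = 7.0,
                                  component_loadings: np.ndarray | None = None,
                                  return_loadings: bool = False):
    """Diploid non-cancer compendium: baseline + rank-``n_components``
    shared structure + gene noise, no regional shifts.

    Used to train the transcriptional components that the FGMP correction
    later removes.  Requires ``n_samples > n_components``.
    """
    if n_samples <= n_components:
        raise ValueError("need n_samples > n_components")
    rng = np.random.default_rng(seed)
    n_genes = genome.n_genes
    values = np.full((n_genes, n_samples), baseline_mean, dtype=float)
    load = None
    if n_components > 0:
        if component_loadings is not None:
            load = np.asarray(component_loadings, float)
            if load.shape != (n_genes, n_components):
                raise ValueError("component_loadings shape mismatch")
        else:
            load = rng.normal(0.0, 1.0, size=(n_genes, n_components))
        activity = rng.normal(0.0, component_sd, size=(n_components, n_samples))
        values += load @ activity
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    sample_ids = [f"ref_s{i:04d}" for i in range(n_samples)]
    vdf = pd.DataFrame(values, index=genome.genes["gene_id"], columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "tissue_class": "normal",
                            "model_label": "reference", "batch_id": "ref"})
    cohort = ExpressionCohort(values=vdf, genes=genome.genes.copy(), samples=samples)
    if return_loadings:
        return cohort, load
    return cohort


# ---------------------------------------------------------------------------
# segmented DNA copy number

@dataclass
class SegmentedCopyNumber:
    """Per-sample piecewise-constant relative copy values plus the true
    per-arm copy deltas that generated them."""
    segments: pd.DataFrame         # sample, chromosome, start, end, value
    true_arm_table: pd.DataFrame   # sample, arm (e.g. "1p"), copy_delta


def simulate_dna_segments(genome: Genome, n_samples: int,
                          arm_events: list[tuple], seed: int = 0,
                          n_extra_splits: int = 2) -> SegmentedCopyNumber:
    """Piecewise-constant relative copy-number profiles with arm-level events.

    ``arm_events`` entries are (arm, direction, probability, copy_delta)
    with arm written "1p"/"4q".  Each chromosome is additionally split at
    ``n_extra_splits`` random points into equal-valued segments, so callers
    must be invariant to value-preserving re-segmentation.
    """
    rng = np.random.default_rng(seed)
    arms = genome.arms.assign(
        key=genome.arms["chromosome"].astype(str) + genome.arms["arm"])
    known = set(arms["key"])
    for ev in arm_events:
        if ev[0] not in known:
            raise ValueError(f"unknown arm {ev[0]!r}")
        if ev[1] not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
    rows, truth_rows = [], []
    for si in range(n_samples):
        sid = f"dna_s{si:03d}"
        deltas = {}
        for arm, direction, prob, delta in arm_events:
            if rng.random() < prob:
                mag = abs(float(delta))
                deltas[arm] = mag if direction == "gain" else -mag
                truth_rows.append({"sample": sid, "arm": arm,
                                   "copy_delta": deltas[arm]})
        for _, chrom in genome.chromosomes.iterrows():
            cname, clen = str(chrom["name"]), int(chrom["length"])
            carms = arms[arms["chromosome"] == cname]
            edges = sorted({0, clen} | set(carms["start"]) | set(carms["end"])
                           | set(int(v) for v in
                                 rng.integers(1, clen, size=n_extra_splits)))
            for s, e in zip(edges[:-1], edges[1:]):
                mid = (s + e) / 2
                hit = carms[(carms["start"] <= mid) & (carms["end"] > mid)]
                key = cname + hit["arm"].iloc[0] if len(hit) else None
                rows.append({"sample": sid, "chromosome": cname,
                             "start": s + 1, "end": e,
                             "value": deltas.get(key, 0.0)})
    segments = pd.DataFrame(rows, columns=["sample", "chromosome", "start",
                                           "end", "value"])
    truth = pd.DataFrame(truth_rows, columns=["sample", "arm", "copy_delta"])
    return SegmentedCopyNumber(segments=segments, true_arm_table=truth)


# ---------------------------------------------------------------------------
# synteny / orthology

def simulate_synteny(genome_a: Genome, genome_b: Genome, block_plan: list,
                     seed: int = 0) -> tuple[list[SyntenyBlock], list[OrthologyPair]]:
    """Build a toy synteny map and the orthology it implies.

    ``block_plan`` entries are (chrom_a, start_a, end_a, chrom_b, start_b,
    end_b, orientation).  Blocks must not overlap within either genome.
    Each species-A gene inside a block is paired with the species-B gene
    nearest its linearly interpolated position inside the block's B side;
    pairs are unique.
    """
    blocks = [SyntenyBlock(str(p[0]), int(p[1]), int(p[2]), str(p[3]),
                           int(p[4]), int(p[5]),
                           p[6] if len(p) > 6 else "same")
              for p in block_plan]
    for side in ("a", "b"):
        by_chrom: dict[str, list] = {}
        for b in blocks:
            by_chrom.setdefault(getattr(b, f"chrom_{side}"), []).append(
                (getattr(b, f"start_{side}"), getattr(b, f"end_{side}")))
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"planned blocks overlap on genome {side} chromosome {chrom}")
    pairs: list[OrthologyPair] = []
    seen = set()
    for b in blocks:
        ga = genome_a.genes_on(b.chrom_a)
        ga = ga[(ga["position"] >= b.start_a) & (ga["position"] < b.end_a)]
        gb = genome_b.genes_on(b.chrom_b)
        gb = gb[(gb["position"] >= b.start_b) & (gb["position"] < b.end_b)]
        if ga.empty or gb.empty:
            continue
        frac = (ga["position"].values - b.start_a) / b.length_a
        if b.orientation == "same":
            target = b.start_b + frac * b.length_b
        else:
            target = b.end_b - frac * b.length_b
        bpos = gb["position"].values
        for gene_a, t in zip(ga["gene_id"], target):
            gene_b = gb["gene_id"].values[int(np.argmin(np.abs(bpos - t)))]
            if (gene_a, gene_b) not in seen:
                seen.add((gene_a, gene_b))
                pairs.append(OrthologyPair(gene_a=gene_a, gene_b=gene_b,
                                           confidence="synthetic"))
    return blocks, pairs
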