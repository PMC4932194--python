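"""Genome scaffolding: chromosomes, genes, cytobands and arms.

The pipeline works at gene resolution (one representative coordinate per
gene) and reports events at cytoband resolution.  A :class:`Genome` bundles
the three coordinate tables every stage needs and enforces the structural
invariants downstream code assumes: cytobands tile each chromosome without
overlap or gap, every gene falls inside exactly one cytoband, and gene
tables are sorted in genome order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "chromosome_sort_key",
    "sort_genome_order",
    "read_cytoband_file",
    "write_cytoband_file",
]

_CHROM_PREFIX = re.compile(r"^chr", re.IGNORECASE)


def normalize_chromosome(name: str) -> str:
    """Strip a ``chr`` prefix so that ``chr1`` and ``1`` compare equal."""
    return _CHROM_PREFIX.sub("", str(name))


def chromosome_sort_key(name: str):
    """Natural ordering: numeric chromosomes first, then X, Y, others."""
    name = normalize_chromosome(name)
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    return (0, special.get(name.upper(), 200), name)


def sort_genome_order(df: pd.DataFrame, chrom_col: str = "chromosome",
                      pos_col: str = "position") -> pd.DataFrame:
    key = df[chrom_col].map(chromosome_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df[pos_col].iloc[i]))
    return df.iloc[order].reset_index(drop=True)


@dataclass
class Genome:
    """Coordinate scaffold shared by all pipeline stages.

    Attributes
    ----------
    chromosomes : DataFrame with columns ``name``, ``length``.
    genes : DataFrame with columns ``gene_id``, ``chromosome``, ``position``,
        ``cytoband`` — sorted by (chromosome, position).
    cytobands : DataFrame with columns ``cytoband``, ``chromosome``,
        ``start``, ``end``, ``arm`` — half-open bp intervals tiling each
        chromosome.
    arms : DataFrame with columns ``chromosome``, ``arm``, ``start``, ``end``.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame
    cytobands: pd.DataFrame
    arms: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.arms is None:
            self.arms = arms_from_cytobands(self.cytobands)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        cb = self.cytobands
        for chrom, grp in cb.groupby("chromosome", sort=False):
            g = grp.sort_values("start")
            if (g["end"].values[:-1] != g["start"].values[1:]).any():
                raise ValueError(f"cytobands on {chrom} do not tile the chromosome")
            length = int(self.chromosomes.set_index("name").loc[str(chrom), "length"])
            if g["start"].iloc[0] != 0 or g["end"].iloc[-1] != length:
                raise ValueError(f"cytobands on {chrom} do not span [0, {length})")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in genome")
        band = self.band_of_genes(self.genes)
        if not (band.values == self.genes["cytoband"].values).all():
            raise ValueError("gene cytoband assignment inconsistent with band intervals")

    def band_of_genes(self, genes: pd.DataFrame) -> pd.Series:
        """Cytoband containing each gene's representative coordinate."""
        out = np.empty(len(genes), dtype=object)
        for chrom, grp in genes.groupby("chromosome", sort=False):
            bands = self.cytobands[self.cytobands["chromosome"] == chrom].sort_values("start")
            if bands.empty:
                raise ValueError(f"no cytobands for chromosome {chrom}")
            idx = np.searchsorted(bands["end"].values, grp["position"].values, side="right")
            idx = np.clip(idx, 0, len(bands) - 1)
            out[genes.index.get_indexer(grp.index)] = bands["cytoband"].values[idx]
        return pd.Series(out, index=genes.index, name="cytoband")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def genes_on(self, chromosome: str) -> pd.DataFrame:
        return self.genes[self.genes["chromosome"] == str(chromosome)]


def arms_from_cytobands(cytobands: pd.DataFrame) -> pd.DataFrame:
    """Derive arm intervals from the band table (band names carry the arm)."""
    rows = []
    for (chrom, arm), grp in cytobands.groupby(["chromosome", "arm"], sort=False):
        rows.append({"chromosome": chrom, "arm": arm,
                     "start": int(grp["start"].min()), "end": int(grp["end"].max())})
    return pd.DataFrame(rows, columns=["chromosome", "arm", "start", "end"])


# -- UCSC-style cytoband I/O ---------------------------------------------

def read_cytoband_file(path) -> pd.DataFrame:
    """Read a UCSC ``cytoBand.txt``-style TSV (chrom, start, end, name, stain).

    Returns a band table with normalized chromosome names and an ``arm``
    column parsed from the leading letter of the band name (``p``/``q``;
    mouse-style ``qA1`` names resolve to ``q``).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "stain"])
    chrom = df["chrom"].map(normalize_chromosome)
    arm = df["name"].astype(str).str[0]
    if not arm.isin(["p", "q"]).all():
        bad = sorted(df.loc[~arm.isin(["p", "q"]), "name"].unique())
        raise ValueError(f"cannot parse arm from band name(s): {bad[:5]}")
    out = pd.DataFrame({
        "cytoband": chrom + df["name"].astype(str),
        "chromosome": chrom,
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "arm": arm,
    })
    # overlap check per chromosome
    for c, grp in out.groupby("chromosome"):
        g = grp.sort_values("start")
        if (g["start"].values[1:] < g["end"].values[:-1]).any():
            raise ValueError(f"overlapping cytobands on chromosome {c}")
    return out.reset_index(drop=True)


def write_cytoband_file(cytobands: pd.DataFrame, path) -> None:
    df = pd.DataFrame({
        "chrom": "chr" + cytobands["chromosome"].astype(str),
        "start": cytobands["start"].astype(int),
        "end": cytobands["end"].astype(int),
        # band name without the chromosome prefix
        "name": [b[len(str(c)):] for b, c in
                 zip(cytobands["cytoband"], cytobands["chromosome"])],
        "stain": "gneg",
    })
    df.to_csv(path, sep="\t", header=False, index=False)
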