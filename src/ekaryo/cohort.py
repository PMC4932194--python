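"""Annotated expression matrices and their TSV serialization.

The carrier object of the pipeline is a gene × sample matrix of log2
expression values together with per-gene genomic coordinates and per-sample
metadata (tissue class, model label, batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import sort_genome_order

TISSUE_CLASSES = ("normal", "premalignant", "tumour", "metastasis",
                  "cell_line", "cellline_tumour")

ANNOT_COLS = ["gene_id", "chromosome", "position"]


@dataclass
class ExpressionCohort:
    """Gene × sample log2 expression with genomic and sample annotation.

    ``values`` is a DataFrame indexed by ``gene_id`` with one column per
    sample; ``genes`` holds ``gene_id``, ``chromosome``, ``position`` (and
    optionally ``cytoband``) sorted in genome order; ``samples`` holds
    ``sample_id``, ``tissue_class``, ``model_label``, ``batch_id``.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame
    reference_mode: str | None = None   # set by center_to_reference

    def __post_init__(self):
        if len(self.values) != len(self.genes):
            raise ValueError("values and genes row counts differ")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("sample columns do not match sample metadata")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_genes(self, keep_mask: np.ndarray) -> "ExpressionCohort":
        """Subset to genes where ``keep_mask`` is True (genome order kept)."""
        return replace(self, values=self.values.loc[keep_mask].copy(),
                       genes=self.genes.loc[keep_mask].reset_index(drop=True))

    def sorted_genome_order(self) -> "ExpressionCohort":
        genes = sort_genome_order(self.genes)
        vals = self.values.loc[genes["gene_id"]].copy()
        return replace(self, values=vals, genes=genes)

    def samples_of_class(self, tissue_class: str) -> list[str]:
        m = self.samples["tissue_class"] == tissue_class
        return list(self.samples.loc[m, "sample_id"])

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path, samples_path=None) -> None:
        """Write as TSV with leading gene_id/chromosome/position columns."""
        out = self.genes[ANNOT_COLS].copy()
        out = pd.concat([out, self.values.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, samples_path=None) -> "ExpressionCohort":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ANNOT_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"expression TSV lacks columns: {missing}")
        genes = df[ANNOT_COLS].copy()
        genes["chromosome"] = genes["chromosome"].astype(str)
        sample_cols = [c for c in df.columns if c not in ANNOT_COLS]
        values = df[sample_cols].copy()
        values.index = genes["gene_id"]
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t")
            samples["sample_id"] = samples["sample_id"].astype(str)
        else:
            samples = pd.DataFrame({
                "sample_id": sample_cols,
                "tissue_class": "tumour",
                "model_label": "unknown",
                "batch_id": "batch0",
            })
        values.columns = values.columns.astype(str)
        return cls(values=values, genes=genes, samples=samples)
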