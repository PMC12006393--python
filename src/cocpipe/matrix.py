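"""Gene x sample count-matrix container with plain-text readers and writers.

Counts are held densely in a pandas DataFrame (genes in rows, samples in
columns); the cohorts this package targets are small (tens to hundreds of
samples), so sparsity machinery would buy nothing. MatrixMarket output uses a
sparse COO view purely for interchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class CountMatrix:
    """Non-negative integer counts with gene/sample identifiers.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index = gene ids, columns =
        sample ids, entries non-negative integers.
    gene_lengths
        Optional per-gene length in base pairs, indexed like ``values``.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        v.index.name = "gene_id"
        v.columns.name = "sample_id"
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (v.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(v.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some genes")

    # -- basic views --------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, keep: list[str] | pd.Index) -> "CountMatrix":
        return CountMatrix(self.values.loc[:, list(keep)], self.gene_lengths)

    # -- plain-text IO ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, gene_lengths: pd.Series | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, gene_lengths)

    def to_mtx_dir(self, outdir: str | Path) -> None:
        """Write matrix.mtx plus genes.tsv / samples.tsv sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(self.values.to_numpy()))
        genes = pd.DataFrame({"gene_id": self.gene_ids})
        if self.gene_lengths is not None:
            genes["length_bp"] = self.gene_lengths.to_numpy()
        genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        pd.DataFrame({"sample_id": self.sample_ids}).to_csv(
            outdir / "samples.tsv", sep="\t", index=False
        )

    @classmethod
    def from_mtx_dir(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        m = spio.mmread(indir / "matrix.mtx").toarray()
        genes = pd.read_csv(indir / "genes.tsv", sep="\t")
        samples = pd.read_csv(indir / "samples.tsv", sep="\t")
        values = pd.DataFrame(
            np.asarray(m), index=pd.Index(genes["gene_id"], name="gene_id"),
            columns=pd.Index(samples["sample_id"], name="sample_id"),
        )
        lengths = None
        if "length_bp" in genes.columns:
            lengths = pd.Series(genes["length_bp"].to_numpy(), index=values.index)
        return cls(values, lengths)
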