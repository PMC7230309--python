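"""Genes x samples TPM expression matrix assembly and TSV round-trip I/O.

The matrix is dense (post-QC bulk RNA-seq corpora have few structural
zeros): memory is roughly ``8 * n_genes * n_samples`` bytes as float64 —
about 0.5 GB for 60k genes x 1000 samples.  Row order follows the
quantifier index; column order follows the manifest, so reruns are
byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .quantification import AbundanceTable

__all__ = [
    "ExpressionMatrix",
    "assemble_matrix",
    "write_matrix",
    "read_matrix",
    "AssemblyError",
]


class AssemblyError(ValueError):
    pass


class ExpressionMatrix:
    """Dense genes (rows) x samples (columns) matrix of TPM values."""

    def __init__(self, values: np.ndarray | pd.DataFrame,
                 gene_ids: list[str] | None = None,
                 sample_ids: list[str] | None = None) -> None:
        if isinstance(values, pd.DataFrame):
            df = values.copy()
        else:
            df = pd.DataFrame(np.asarray(values, dtype=float),
                              index=list(gene_ids), columns=list(sample_ids))
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("matrix values must be finite")
        if np.any(arr < 0):
            raise ValueError("matrix values must be non-negative")
        df.index.name = "gene"
        self._df = df.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self._df.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self._df.loc[gene_id].to_numpy()

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self._df.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._df.loc[gene_ids])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._df.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._df[sample_ids])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (self.gene_ids == other.gene_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values))


def assemble_matrix(abundances: Mapping[str, AbundanceTable],
                    pass_list: list[str]) -> ExpressionMatrix:
    """Compile per-run abundance tables into one TPM matrix.

    Columns are restricted to ``pass_list`` in its order; rows keep the gene
    order of the first table (the quantifier index order, identical across
    runs by construction).  A run whose gene set differs from the index is a
    hard error naming the accession.
    """
    if not pass_list:
        raise AssemblyError("pass list is empty")
    missing = [acc for acc in pass_list if acc not in abundances]
    if missing:
        raise AssemblyError(f"no abundance table for passing run(s) {missing}")
    reference = abundances[pass_list[0]].ids
    columns = {}
    for acc in pass_list:
        table = abundances[acc]
        if table.ids != reference:
            raise AssemblyError(
                f"gene set of {acc} differs from the quantifier index order"
            )
        columns[acc] = table.tpm
    values = np.column_stack([columns[acc] for acc in pass_list])
    return ExpressionMatrix(values, gene_ids=list(reference),
                            sample_ids=list(pass_list))


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: first column ``gene``, then run accessions.

    Values are serialized with ``repr`` round-trip precision so that
    ``read_matrix(write_matrix(M))`` reproduces M exactly.
    """
    df = matrix.frame
    with Path(path).open("w") as fh:
        fh.write("gene\t" + "\t".join(df.columns) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row)
                     + "\n")


def read_matrix(path: str | Path) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot parse matrix TSV: {exc}") from exc
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate gene or sample labels in matrix TSV")
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)
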