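"""Expression dataset container and on-disk formats.

A cohort is a list of :class:`ExpressionDataset`, one per study dataset.
Each dataset carries a raw count matrix and a matched TPM matrix
(genes in rows, samples/cells in columns) plus a per-sample metadata
table. Bulk datasets are written as TSV matrices; single-cell datasets
as MatrixMarket coordinate triplets with genes/barcodes index files.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

BULK = "bulk"
SINGLE_CELL = "single_cell"

MODALITIES = (BULK, SINGLE_CELL)


@dataclass
class ExpressionDataset:
    """One dataset of the cohort: counts + TPM + sample metadata.

    Parameters
    ----------
    name : str
        Dataset identifier (e.g. ``"bulk-iN-1"``).
    modality : str
        ``"bulk"`` or ``"single_cell"``.
    counts : pandas.DataFrame
        Raw counts, genes in rows, samples/cells in columns.
    tpm : pandas.DataFrame
        Transcripts-per-million matrix aligned with ``counts``
        (every column sums to 1e6).
    samples : pandas.DataFrame
        Per-sample metadata indexed by sample/cell id. Expected columns:
        ``subject``, ``condition`` and, where available, ``mapping_rate``.
    umi_based : bool
        True for droplet single-cell data (UMI counts; the fractional
        housekeeping QC dialect and the UMI doublet rule apply).
    gene_lengths : pandas.Series or None
        Effective gene lengths in bases used to recompute TPM from
        counts (constant 1 kb when None).
    """

    name: str
    modality: str
    counts: pd.DataFrame
    tpm: pd.DataFrame
    samples: pd.DataFrame
    umi_based: bool = False
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if not self.counts.index.equals(self.tpm.index):
            raise ValueError(f"dataset {self.name}: counts/TPM gene indices differ")
        if not self.counts.columns.equals(self.tpm.columns):
            raise ValueError(f"dataset {self.name}: counts/TPM sample columns differ")
        missing = self.counts.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(
                f"dataset {self.name}: samples table missing metadata for {list(missing)[:5]}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, keep: pd.Index | list) -> "ExpressionDataset":
        """Return a copy restricted to the given sample/cell ids (order kept)."""
        keep = pd.Index(keep)
        return ExpressionDataset(
            name=self.name,
            modality=self.modality,
            counts=self.counts.loc[:, keep].copy(),
            tpm=self.tpm.loc[:, keep].copy(),
            samples=self.samples.loc[keep].copy(),
            umi_based=self.umi_based,
            gene_lengths=self.gene_lengths,
        )


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts per million from a count matrix.

    Counts are divided by gene length (kb) and each column rescaled to sum
    to 1e6. With constant lengths (the default 1 kb) this equals CPM.
    All-zero columns stay all-zero rather than producing NaN.
    """
    if counts.empty:
        raise ValueError("cannot compute TPM of an empty matrix")
    if gene_lengths is None:
        rate = counts.astype(float)
    else:
        lengths = gene_lengths.reindex(counts.index)
        if lengths.isna().any():
            raise ValueError("gene_lengths missing entries for some genes")
        rate = counts.astype(float).div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0).to_numpy()
    scale = np.divide(1e6, colsum, out=np.zeros_like(colsum, dtype=float),
                      where=colsum > 0)
    return rate * scale


# ---------------------------------------------------------------------------
# TSV / MTX readers and writers
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path: str) -> None:
    """Write a genes-by-samples matrix as TSV (header = sample ids)."""
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_mtx(matrix: pd.DataFrame, prefix: str) -> list[str]:
    """Write a sparse matrix as MatrixMarket triplet plus index files.

    Produces ``<prefix>.mtx`` (1-based coordinate format), ``<prefix>.genes.tsv``
    and ``<prefix>.barcodes.tsv``. Returns the list of files written.
    """
    sparse = scipy.sparse.coo_matrix(matrix.to_numpy())
    mtx_path = f"{prefix}.mtx"
    # mmwrite appends .mtx itself only when missing; write through a buffer to
    # keep the file ASCII text regardless of dtype.
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sparse)
    with open(mtx_path, "wb") as fh:
        fh.write(buf.getvalue())
    genes_path = f"{prefix}.genes.tsv"
    barcodes_path = f"{prefix}.barcodes.tsv"
    pd.Series(matrix.index).to_csv(genes_path, sep="\t", index=False, header=False)
    pd.Series(matrix.columns).to_csv(barcodes_path, sep="\t", index=False, header=False)
    return [mtx_path, genes_path, barcodes_path]


def read_matrix_mtx(prefix: str) -> pd.DataFrame:
    mat = scipy.io.mmread(f"{prefix}.mtx").toarray()
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(f"{prefix}.barcodes.tsv", sep="\t", header=None)[0].astype(str)
    df = pd.DataFrame(
        mat, index=pd.Index(genes, name="gene"),
        columns=pd.Index(barcodes.to_numpy(), name=None),
    )
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.round().astype(np.int64)
    return df


def write_dataset(dataset: ExpressionDataset, dir_path: str) -> list[str]:
    """Write one dataset under ``dir_path`` (TSV for bulk, MTX for single-cell)."""
    if dataset.counts.shape[0] == 0:
        raise ValueError(f"dataset {dataset.name}: empty gene list, refusing to write")
    os.makedirs(dir_path, exist_ok=True)
    base = os.path.join(dir_path, dataset.name)
    files: list[str] = []
    if dataset.modality == SINGLE_CELL:
        files += write_matrix_mtx(dataset.counts, f"{base}.counts")
        files += write_matrix_mtx(dataset.tpm, f"{base}.tpm")
    else:
        write_matrix_tsv(dataset.counts, f"{base}.counts.tsv")
        write_matrix_tsv(dataset.tpm, f"{base}.tpm.tsv")
        files += [f"{base}.counts.tsv", f"{base}.tpm.tsv"]
    meta_path = f"{base}.samples.tsv"
    meta = dataset.samples.copy()
    meta.insert(0, "modality", dataset.modality)
    meta.insert(1, "umi_based", dataset.umi_based)
    meta.to_csv(meta_path, sep="\t", index_label="sample")
    files.append(meta_path)
    return files


def read_dataset(dir_path: str, name: str) -> ExpressionDataset:
    base = os.path.join(dir_path, name)
    meta = pd.read_csv(f"{base}.samples.tsv", sep="\t", index_col=0)
    modality = str(meta["modality"].iloc[0])
    umi_based = bool(meta["umi_based"].iloc[0])
    meta = meta.drop(columns=["modality", "umi_based"])
    meta.index = meta.index.astype(str)
    if modality == SINGLE_CELL:
        counts = read_matrix_mtx(f"{base}.counts")
        tpm = read_matrix_mtx(f"{base}.tpm").astype(float)
    else:
        counts = read_matrix_tsv(f"{base}.counts.tsv")
        tpm = read_matrix_tsv(f"{base}.tpm.tsv")
    counts.columns = counts.columns.astype(str)
    tpm.columns = tpm.columns.astype(str)
    return ExpressionDataset(
        name=name, modality=modality, counts=counts, tpm=tpm,
        samples=meta, umi_based=umi_based,
    )
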