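"""Readers and writers for 10X-style per-sample artifacts.

Two on-disk formats are supported:

* a MatrixMarket coordinate triplet file (``matrix.mtx``/``matrix.mtx.gz``)
  with gene and barcode sidecar tables (``features.tsv``/``genes.tsv`` and
  ``barcodes.tsv``, plain or gzipped), and
* the ``filtered_contig_annotations.csv`` contig-table dialect.

MatrixMarket coordinates are 1-based per the standard; all in-memory indices
are 0-based.  Barcode suffixes (e.g. ``-1``) are preserved verbatim and are
significant when matching barcodes between libraries.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DimensionError, FormatError, InvariantError

__all__ = [
    "ExpressionMatrix",
    "ContigRecord",
    "read_matrix",
    "write_matrix",
    "read_contigs",
    "write_contigs",
    "concat_cells",
    "CONTIG_COLUMNS",
]

_MATRIX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")

#: Mandatory columns of the contig-annotation dialect, in canonical order.
CONTIG_COLUMNS = [
    "barcode",
    "is_cell",
    "high_confidence",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
    "productive",
    "raw_clonotype_id",
]


@dataclass
class ExpressionMatrix:
    """Gene x cell UMI count matrix with identifier sidecars.

    ``counts`` is stored as a CSR sparse matrix of non-negative integers with
    one row per gene and one column per cell barcode.
    """

    gene_ids: List[str]
    barcodes: List[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def validate(self) -> "ExpressionMatrix":
        """Raise :class:`InvariantError` unless all invariants hold."""
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise InvariantError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvariantError("gene_ids are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InvariantError("barcodes are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise InvariantError("counts contain negative entries")
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise InvariantError("counts contain non-integral entries")
        return self

    def subset_cells(self, col_idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(col_idx, dtype=int)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            barcodes=[self.barcodes[i] for i in idx],
            counts=self.counts[:, idx].tocsr(),
        )

    def subset_genes(self, row_idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(row_idx, dtype=int)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            barcodes=list(self.barcodes),
            counts=self.counts[idx, :].tocsr(),
        )


def concat_cells(
    mats: Sequence[ExpressionMatrix], barcode_prefixes: Optional[Sequence[str]] = None
) -> ExpressionMatrix:
    """Column-concatenate matrices sharing the same gene universe.

    Optional per-matrix prefixes (joined with ':') keep barcodes unique when
    pooling samples that may reuse barcode sequences.
    """
    if not mats:
        raise FormatError("concat_cells needs at least one matrix")
    gene_ids = mats[0].gene_ids
    for m in mats[1:]:
        if m.gene_ids != gene_ids:
            raise DimensionError("matrices do not share the same gene universe")
    if barcode_prefixes is None:
        barcodes = [b for m in mats for b in m.barcodes]
    else:
        barcodes = [
            f"{p}:{b}" for m, p in zip(mats, barcode_prefixes) for b in m.barcodes
        ]
    counts = sp.hstack([m.counts for m in mats]).tocsr()
    return ExpressionMatrix(list(gene_ids), barcodes, counts).validate()


@dataclass
class ContigRecord:
    """One TCR chain observation attached to a cell barcode."""

    barcode: str
    is_cell: bool = True
    high_confidence: bool = True
    chain: str = "None"
    v_gene: str = ""
    d_gene: str = ""
    j_gene: str = ""
    c_gene: str = ""
    cdr3_aa: str = ""
    cdr3_nt: str = ""
    reads: int = 0
    umis: int = 0
    productive: bool = False
    raw_clonotype_id: str = ""


def _find_file(dir_path: Path, candidates: Iterable[str], what: str) -> Path:
    for name in candidates:
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(
        f"no {what} file found in {dir_path} (looked for {', '.join(candidates)})"
    )


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_sidecar_column(path: Path) -> List[str]:
    """First tab-separated column of a sidecar table, one entry per line."""
    out: List[str] = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_matrix(dir_path: os.PathLike | str) -> ExpressionMatrix:
    """Read a MatrixMarket triplet directory into an :class:`ExpressionMatrix`.

    Entries absent from the triplet file are zero.  Raises
    :class:`FormatError` when a file is missing and :class:`DimensionError`
    when the triplet header disagrees with the sidecar tables.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FormatError(f"not a directory: {dir_path}")
    mtx_path = _find_file(dir_path, _MATRIX_NAMES, "matrix")
    feat_path = _find_file(dir_path, _FEATURE_NAMES, "feature sidecar")
    bc_path = _find_file(dir_path, _BARCODE_NAMES, "barcode sidecar")

    with _open_maybe_gzip(mtx_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    gene_ids = _read_sidecar_column(feat_path)
    barcodes = _read_sidecar_column(bc_path)

    if mat.shape != (len(gene_ids), len(barcodes)):
        raise DimensionError(
            f"matrix header declares {mat.shape[0]} x {mat.shape[1]} but sidecars "
            f"list {len(gene_ids)} genes and {len(barcodes)} barcodes"
        )
    m = ExpressionMatrix(
        gene_ids=gene_ids, barcodes=barcodes, counts=sp.csr_matrix(mat, dtype=np.int64)
    )
    return m.validate()


def write_matrix(m: ExpressionMatrix, dir_path: os.PathLike | str) -> Path:
    """Write ``m`` as a MatrixMarket triplet directory readable by
    :func:`read_matrix`.  Refuses to write a matrix violating its invariants."""
    m.validate()
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    coo = m.counts.tocoo()
    with open(dir_path / "matrix.mtx", "w", newline="\n") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{m.n_genes} {m.n_cells} {coo.nnz}\n")
        # 1-based coordinates per the MatrixMarket standard
        order = np.lexsort((coo.row, coo.col))
        for i in order:
            fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {int(coo.data[i])}\n")
    with open(dir_path / "features.tsv", "w", newline="\n") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w", newline="\n") as fh:
        for b in m.barcodes:
            fh.write(f"{b}\n")
    return dir_path


_TRUE_STRINGS = {"true", "1", "yes"}


def _parse_flag(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in _TRUE_STRINGS


def read_contigs(csv_path: os.PathLike | str) -> List[ContigRecord]:
    """Parse a contig annotation CSV into :class:`ContigRecord` objects.

    ``True``/``true``/``TRUE`` all parse as flag true; empty gene fields are
    preserved as empty strings; extra columns are ignored.  A missing
    mandatory column raises :class:`FormatError` naming the column.
    """
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FormatError(f"contig file not found: {csv_path}")
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    for col in CONTIG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"contig table {csv_path} lacks mandatory column '{col}'")
    records: List[ContigRecord] = []
    for row in df.itertuples(index=False):
        records.append(
            ContigRecord(
                barcode=row.barcode,
                is_cell=_parse_flag(row.is_cell),
                high_confidence=_parse_flag(row.high_confidence),
                chain=row.chain if row.chain else "None",
                v_gene=row.v_gene,
                d_gene=row.d_gene,
                j_gene=row.j_gene,
                c_gene=row.c_gene,
                cdr3_aa=row.cdr3,
                cdr3_nt=row.cdr3_nt,
                reads=int(row.reads) if row.reads else 0,
                umis=int(row.umis) if row.umis else 0,
                productive=_parse_flag(row.productive),
                raw_clonotype_id=row.raw_clonotype_id,
            )
        )
    return records


def write_contigs(records: Sequence[ContigRecord], csv_path: os.PathLike | str) -> Path:
    """Write contig records in the ``filtered_contig_annotations.csv`` dialect."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        if r.reads < 0 or r.umis < 0:
            raise InvariantError("reads and umis must be non-negative")
        rows.append(
            {
                "barcode": r.barcode,
                "is_cell": "True" if r.is_cell else "False",
                "high_confidence": "True" if r.high_confidence else "False",
                "chain": r.chain,
                "v_gene": r.v_gene,
                "d_gene": r.d_gene,
                "j_gene": r.j_gene,
                "c_gene": r.c_gene,
                "cdr3": r.cdr3_aa,
                "cdr3_nt": r.cdr3_nt,
                "reads": r.reads,
                "umis": r.umis,
                "productive": "True" if r.productive else "False",
                "raw_clonotype_id": r.raw_clonotype_id,
            }
        )
    pd.DataFrame(rows, columns=CONTIG_COLUMNS).to_csv(csv_path, index=False)
    return csv_path
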