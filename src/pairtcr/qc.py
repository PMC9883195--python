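"""Quality-control filtering and marker-score cell typing.

QC keeps genes expressed in at least ``min_cells_per_gene`` cells and cells
detecting strictly more than ``min_genes_exclusive`` and strictly fewer than
``max_genes_exclusive`` genes (an inclusive variant is available by flag).
The original analysis additionally removed mitochondrial outliers by eye;
that subjective step is exposed here as an optional numeric ``mito_max``
threshold and disabled by default.

Cell typing scores each marker set as the mean z-scored log-normalised
expression of its markers and assigns the argmax label; this is an automated
stand-in for manual cluster annotation, and externally supplied labels are
accepted everywhere downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_tenx import ExpressionMatrix

__all__ = [
    "CellMeta",
    "QCReport",
    "qc_filter",
    "log_normalize",
    "assign_cell_types",
    "composition_table",
]

logger = logging.getLogger(__name__)

VALID_GROUPS = ("normal", "sephin1")
VALID_TISSUES = ("blood_d0", "blood_d15", "tumor_d15")


@dataclass
class CellMeta:
    barcode: str
    sample_id: str
    group: str
    tissue: str
    cell_type: str = "unassigned"
    n_genes_detected: int = 0
    mito_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ConfigError(f"unknown group '{self.group}'")
        if self.tissue not in VALID_TISSUES:
            raise ConfigError(f"unknown tissue '{self.tissue}'")


@dataclass
class QCReport:
    genes_in: int
    genes_out: int
    cells_in: int
    cells_out: int
    rounds: int


def _mito_fractions(m: ExpressionMatrix) -> np.ndarray:
    mito_rows = [i for i, g in enumerate(m.gene_ids) if g.lower().startswith("mt-")]
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if not mito_rows:
        return np.zeros(m.n_cells)
    mito = np.asarray(m.counts[mito_rows, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    return frac


def qc_filter(
    m: ExpressionMatrix,
    min_cells_per_gene: int = 2,
    min_genes_exclusive: int = 100,
    max_genes_exclusive: int = 4000,
    mito_max: Optional[float] = None,
    inclusive_bounds: bool = False,
    return_report: bool = False,
):
    """Apply the gene filter, then the cell filter, iterated to a fixed point.

    Iterating makes the operation idempotent: removing cells can drop a gene
    below the support threshold, which a second round then removes.  Emits an
    explicit warning (never a silent empty result) if every cell is removed.
    """
    m.validate()
    genes_in, cells_in = m.n_genes, m.n_cells
    rounds = 0
    while True:
        rounds += 1
        cells_per_gene = np.asarray((m.counts > 0).sum(axis=1)).ravel()
        keep_genes = np.flatnonzero(cells_per_gene >= min_cells_per_gene)
        m2 = m.subset_genes(keep_genes) if len(keep_genes) < m.n_genes else m

        genes_per_cell = np.asarray((m2.counts > 0).sum(axis=0)).ravel()
        if inclusive_bounds:
            keep = (genes_per_cell >= min_genes_exclusive) & (
                genes_per_cell <= max_genes_exclusive
            )
        else:
            keep = (genes_per_cell > min_genes_exclusive) & (
                genes_per_cell < max_genes_exclusive
            )
        if mito_max is not None:
            keep &= _mito_fractions(m2) <= mito_max
        keep_cells = np.flatnonzero(keep)
        m2 = m2.subset_cells(keep_cells) if len(keep_cells) < m2.n_cells else m2

        changed = (m2.n_genes, m2.n_cells) != (m.n_genes, m.n_cells)
        m = m2
        if not changed:
            break
    if m.n_cells == 0:
        warnings.warn("qc_filter removed every cell", UserWarning, stacklevel=2)
    report = QCReport(genes_in, m.n_genes, cells_in, m.n_cells, rounds)
    logger.info(
        "qc_filter: genes %d -> %d, cells %d -> %d (%d round(s))",
        genes_in, m.n_genes, cells_in, m.n_cells, rounds,
    )
    if return_report:
        return m, report
    return m


def log_normalize(m: ExpressionMatrix, scale: float = 1e4) -> np.ndarray:
    """Counts scaled to ``scale`` per cell, then log1p.  Dense genes x cells."""
    x = np.asarray(m.counts.todense(), dtype=float)
    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(x / totals * scale)


def assign_cell_types(
    m: ExpressionMatrix,
    marker_sets: Mapping[str, Sequence[str]],
) -> List[str]:
    """Per-cell argmax over marker-set scores.

    Score of a set = mean over its markers of z-scored (across cells)
    log-normalised expression.  Ties break by set order; cells whose scores
    are all <= 0 are labelled ``unassigned``.  Markers missing from the matrix
    are dropped with a logged warning; duplicate listings within a set are
    collapsed, so the result is invariant to duplicated markers and to gene
    row order.
    """
    if not marker_sets:
        raise ConfigError("marker_sets is empty")
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    x = log_normalize(m)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    labels_order = list(marker_sets)
    scores = np.full((len(labels_order), m.n_cells), -np.inf)
    for i, label in enumerate(labels_order):
        rows = []
        seen = set()
        for g in marker_sets[label]:
            if g in seen:
                continue
            seen.add(g)
            if g in gene_index:
                rows.append(gene_index[g])
            else:
                logger.warning("marker %s for %s absent from matrix; dropped", g, label)
        if rows:
            scores[i] = z[rows, :].mean(axis=0)
    best = scores.argmax(axis=0)
    best_score = scores[best, np.arange(m.n_cells)]
    return [
        labels_order[b] if s > 0 else "unassigned"
        for b, s in zip(best, best_score)
    ]


def composition_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Cell-type percentage per (tissue, group) stratum; rows sum to 100.

    ``meta`` needs columns tissue, group and cell_type.  Empty strata are
    simply absent.  Invariant to input row order.
    """
    required = {"tissue", "group", "cell_type"}
    missing = required - set(meta.columns)
    if missing:
        raise ConfigError(f"metadata lacks columns: {sorted(missing)}")
    counts = (
        meta.groupby(["tissue", "group", "cell_type"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct
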