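"""Clonotype calling, frequency computation, expansion binning and ranking.

A clonotype's frequency is its clone count over all clones of the sample
(TCR+ cells only), and bins are half-open intervals (lo, hi]:

    hyperexpanded (0.1, 1] | large (0.01, 0.1] | medium (0.001, 0.01]
    | small (1e-4, 0.001]  | rare (0, 1e-4]

``rare`` extends the published scheme below its smallest bound so frequency
mass is conserved rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InvariantError
from .io_tenx import ContigRecord

__all__ = [
    "BinThresholds",
    "ClonotypeEntry",
    "ClonotypeTable",
    "BIN_LABELS",
    "call_clonotypes",
    "compute_frequencies",
    "bin_clonotypes",
    "cell_bin_labels",
    "rank_clonotypes",
    "bin_composition",
]

logger = logging.getLogger(__name__)

BIN_LABELS = ("hyperexpanded", "large", "medium", "small", "rare")


@dataclass(frozen=True)
class BinThresholds:
    rare_lo: float = 1e-4
    small_hi: float = 1e-3
    medium_hi: float = 1e-2
    large_hi: float = 0.1
    hyper_hi: float = 1.0

    def __post_init__(self) -> None:
        edges = (self.rare_lo, self.small_hi, self.medium_hi, self.large_hi, self.hyper_hi)
        if not all(a < b for a, b in zip(edges, edges[1:])):
            raise InvariantError("bin thresholds must be strictly increasing")

    def classify(self, f: float) -> str:
        """Half-open (lo, hi] membership; f must lie in (0, hyper_hi]."""
        if not 0.0 < f <= self.hyper_hi:
            raise InvariantError(f"frequency {f} outside (0, {self.hyper_hi}]")
        if f > self.large_hi:
            return "hyperexpanded"
        if f > self.medium_hi:
            return "large"
        if f > self.small_hi:
            return "medium"
        if f > self.rare_lo:
            return "small"
        return "rare"


@dataclass
class ClonotypeEntry:
    key: str
    barcodes: List[str]
    clone_count: int
    frequency: Optional[float] = None
    bin: Optional[str] = None
    n_chains: int = 2  # 1 flags single-chain (TRA-only or TRB-only) clonotypes


@dataclass
class ClonotypeTable:
    sample_id: str
    entries: Dict[str, ClonotypeEntry] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return sum(e.clone_count for e in self.entries.values())

    def barcode_to_key(self) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for e in self.entries.values():
            for bc in e.barcodes:
                out[bc] = e.key
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample_id,
                "clonotype_key": e.key,
                "clone_count": e.clone_count,
                "frequency": e.frequency,
                "bin": e.bin,
                "n_chains": e.n_chains,
            }
            for e in sorted(self.entries.values(), key=lambda e: e.key)
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "clonotype_key", "clone_count", "frequency", "bin", "n_chains"],
        )

    def validate(self) -> "ClonotypeTable":
        freqs = [e.frequency for e in self.entries.values()]
        if self.entries and all(f is not None for f in freqs):
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise InvariantError("clonotype frequencies do not sum to 1")
        return self


def _chain_key(rec: ContigRecord, strategy: str) -> str:
    cdr3 = rec.cdr3_nt if strategy == "nt+gene" else rec.cdr3_aa
    return f"{rec.chain}:{rec.v_gene}:{rec.j_gene}:{cdr3}"


def call_clonotypes(
    contigs: Iterable[ContigRecord],
    sample_id: str = "",
    strategy: str = "nt+gene",
) -> ClonotypeTable:
    """Group one sample's contigs into clonotypes (frequencies not yet set).

    Retains records with ``is_cell``, ``high_confidence`` and ``productive``
    all true and chain in {TRA, TRB}; per barcode and chain only the
    highest-UMI record contributes (ties broken by higher reads, then by
    lexicographically smallest cdr3_nt).  The clonotype key is the sorted
    concatenation of ``chain:v_gene:j_gene:cdr3`` over the barcode's retained
    chains, at nucleotide (default) or amino-acid level.  Barcodes with a
    single retained chain are keyed by that chain and flagged via
    ``n_chains=1``.
    """
    if strategy not in ("nt+gene", "aa"):
        raise InvariantError(f"unknown clonotype strategy '{strategy}'")
    best: Dict[Tuple[str, str], ContigRecord] = {}
    for rec in contigs:
        if not (rec.is_cell and rec.high_confidence and rec.productive):
            continue
        if rec.chain not in ("TRA", "TRB"):
            continue
        slot = (rec.barcode, rec.chain)
        cur = best.get(slot)
        if cur is None:
            best[slot] = rec
            continue
        better = (rec.umis, rec.reads, _neg_lex(rec.cdr3_nt)) > (
            cur.umis, cur.reads, _neg_lex(cur.cdr3_nt)
        )
        if better:
            best[slot] = rec

    per_barcode: Dict[str, List[ContigRecord]] = {}
    for (bc, _chain), rec in best.items():
        per_barcode.setdefault(bc, []).append(rec)

    table = ClonotypeTable(sample_id=sample_id)
    for bc in sorted(per_barcode):
        recs = per_barcode[bc]
        key = "|".join(sorted(_chain_key(r, strategy) for r in recs))
        entry = table.entries.get(key)
        if entry is None:
            table.entries[key] = ClonotypeEntry(
                key=key, barcodes=[bc], clone_count=1, n_chains=len(recs)
            )
        else:
            entry.barcodes.append(bc)
            entry.clone_count += 1
    return table


class _neg_lex(str):
    """Inverts lexicographic comparison so 'smaller cdr3_nt wins' fits a
    single descending tuple comparison."""

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def compute_frequencies(t: ClonotypeTable) -> ClonotypeTable:
    """Frequency = clone_count / total clones of the sample (TCR+ cells)."""
    total = t.n_cells
    out = ClonotypeTable(sample_id=t.sample_id)
    for key, e in t.entries.items():
        out.entries[key] = replace(e, frequency=e.clone_count / total if total else None)
    return out


def bin_clonotypes(
    t: ClonotypeTable, thresholds: BinThresholds = BinThresholds()
) -> ClonotypeTable:
    """Attach an expansion bin to every clonotype; requires frequencies."""
    out = ClonotypeTable(sample_id=t.sample_id)
    for key, e in t.entries.items():
        if e.frequency is None:
            raise InvariantError(
                "bin_clonotypes requires frequencies; run compute_frequencies first"
            )
        out.entries[key] = replace(e, bin=thresholds.classify(e.frequency))
    return out.validate()


def cell_bin_labels(
    t: ClonotypeTable, barcodes: Iterable[str]
) -> Dict[str, str]:
    """Per-cell bin labels: TCR+ cells inherit their clonotype's bin, cells
    absent from the table get ``none``.  Barcodes present in the table but not
    in ``barcodes`` are logged as orphans and excluded."""
    barcode_set = set(barcodes)
    labels = {bc: "none" for bc in barcode_set}
    orphans = 0
    for e in t.entries.values():
        if e.bin is None:
            raise InvariantError("cell_bin_labels requires a binned table")
        for bc in e.barcodes:
            if bc in barcode_set:
                labels[bc] = e.bin
            else:
                orphans += 1
    if orphans:
        logger.warning(
            "cell_bin_labels: %d contig barcode(s) missing from metadata; excluded",
            orphans,
        )
    return labels


def rank_clonotypes(t: ClonotypeTable) -> List[ClonotypeEntry]:
    """Descending by frequency, ties broken lexicographically by key."""
    for e in t.entries.values():
        if e.frequency is None:
            raise InvariantError("rank_clonotypes requires frequencies")
    return sorted(t.entries.values(), key=lambda e: (-e.frequency, e.key))


def bin_composition(
    tables: Mapping[str, ClonotypeTable],
    sample_strata: Mapping[str, Tuple[str, str]],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of clonotypes and of cells per bin for each (tissue, group).

    ``sample_strata`` maps sample_id -> (tissue, group).  Returns
    (clonotype-level, cell-level) tables whose rows sum to 100 over the bins
    present; strata with zero TCR+ cells are omitted with a warning.
    """
    clono_counts: Dict[Tuple[str, str], Dict[str, int]] = {}
    cell_counts: Dict[Tuple[str, str], Dict[str, int]] = {}
    for sid, table in tables.items():
        stratum = sample_strata[sid]
        cc = clono_counts.setdefault(stratum, {b: 0 for b in BIN_LABELS})
        lc = cell_counts.setdefault(stratum, {b: 0 for b in BIN_LABELS})
        for e in table.entries.values():
            if e.bin is None:
                raise InvariantError("bin_composition requires binned tables")
            cc[e.bin] += 1
            lc[e.bin] += e.clone_count

    def _to_pct(counts: Dict[Tuple[str, str], Dict[str, int]]) -> pd.DataFrame:
        rows = {}
        for stratum in sorted(counts):
            total = sum(counts[stratum].values())
            if total == 0:
                logger.warning("bin_composition: stratum %s has no TCR+ cells; omitted",
                               stratum)
                continue
            rows[stratum] = {b: counts[stratum][b] / total * 100.0 for b in BIN_LABELS}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(BIN_LABELS))
        df.index = pd.MultiIndex.from_tuples(df.index, names=["tissue", "group"]) if len(df) else df.index
        return df

    return _to_pct(clono_counts), _to_pct(cell_counts)
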