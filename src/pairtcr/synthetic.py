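"""Synthetic paired GEX+VDJ cohort generator with planted ground truth.

Builds a two-arm cohort (``normal`` vs ``sephin1``) across up to three
tissues with:

* negative-binomial counts, marker genes elevated ``marker_fold``-fold in
  their owning cell type, and configurable additive log-fold shifts on
  signature gene sets per (group, tissue);
* skewed clone-size distributions for T/NKT cells, with the skew damped by
  ``expansion_damp`` in the treated arm;
* a planted per-tissue rate of TCR transfer from T cells to macrophages
  (donor clonotype chosen proportional to clone size, Cd8 vs Cd4 donors mixed
  by ``trog_donor_mix``); the donor's contig rows are copied verbatim under
  the macrophage's barcode, modelling mRNA-level TCR presence.

Randomness: one independent RNG stream per sample, derived from
``SeedSequence([seed, sha256(stream_name)[:8]])`` so outputs do not depend on
sample generation order.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .defaults import (
    DEFAULT_MARKER_SETS,
    DEFAULT_SIGNATURE_SETS,
    GROUPS,
    TISSUES,
    T_CELL_TYPES,
)
from .errors import ConfigError
from .io_tenx import ContigRecord, ExpressionMatrix, write_contigs, write_matrix

__all__ = [
    "CohortConfig",
    "GroundTruthManifest",
    "Cohort",
    "SampleData",
    "generate_clone_sizes",
    "generate_cohort",
    "write_cohort",
]

# one representative codon per amino acid (no stop codons can arise)
_AA_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "AGT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_AA_ALPHABET = sorted(_AA_CODON)


def _stream_seed(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream: SeedSequence([seed, first 8 bytes of sha256(name)])."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


@dataclass
class CohortConfig:
    n_samples_per_arm: int = 2
    tissues: Tuple[str, ...] = TISSUES
    n_cells_per_sample: int = 500
    cell_type_proportions: Optional[Dict[Tuple[str, str], Dict[str, float]]] = None
    n_genes: int = 2000
    nb_mean: float = 0.3
    nb_dispersion: float = 2.0
    marker_fold: float = 5.0
    sig_shift: Dict[Tuple[str, str, str], float] = field(default_factory=dict)
    clone_dist: Dict[str, object] = field(
        default_factory=lambda: {"type": "power_law", "exponent": 2.0}
    )
    expansion_damp: float = 1.0
    trog_rate: Dict[str, float] = field(default_factory=dict)
    trog_donor_mix: float = 0.8
    marker_sets: Dict[str, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_SETS.items()}
    )
    signature_sets: Dict[str, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURE_SETS.items()}
    )
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_samples_per_arm < 1:
            raise ConfigError("n_samples_per_arm must be >= 1")
        if self.n_cells_per_sample < 1:
            raise ConfigError("n_cells_per_sample must be >= 1")
        for t in self.tissues:
            if t not in TISSUES:
                raise ConfigError(f"unknown tissue '{t}'")
        props = self.proportions()
        for tissue in self.tissues:
            for group in GROUPS:
                key = (tissue, group)
                if key not in props:
                    raise ConfigError(f"cell_type_proportions missing stratum {key}")
                total = sum(props[key].values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"cell_type_proportions for {key} sum to {total}, not 1"
                    )
        for tissue, rate in self.trog_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"trog_rate[{tissue}]={rate} outside [0,1]")
        if not 0.0 <= self.trog_donor_mix <= 1.0:
            raise ConfigError("trog_donor_mix outside [0,1]")
        if not 0.0 < self.expansion_damp <= 1.0:
            raise ConfigError("expansion_damp outside (0,1]")
        return self

    def proportions(self) -> Dict[Tuple[str, str], Dict[str, float]]:
        if self.cell_type_proportions is not None:
            return self.cell_type_proportions
        blood = {
            "Cd4_T": 0.25, "Cd8_T": 0.25, "NKT": 0.05,
            "NK": 0.10, "B": 0.25, "Macrophage": 0.10,
        }
        tumor = {
            "Cd4_T": 0.20, "Cd8_T": 0.25, "NKT": 0.05,
            "NK": 0.05, "B": 0.05, "Macrophage": 0.40,
        }
        props = {}
        for tissue in self.tissues:
            base = tumor if tissue == "tumor_d15" else blood
            for group in GROUPS:
                props[(tissue, group)] = dict(base)
        return props

    def sample_ids(self) -> List[str]:
        return [
            f"{group}_{tissue}_{rep}"
            for group in GROUPS
            for tissue in self.tissues
            for rep in range(1, self.n_samples_per_arm + 1)
        ]

    def gene_universe(self) -> List[str]:
        """Named marker/signature genes first, then numbered filler genes."""
        named: List[str] = []
        seen = set()
        for genes in list(self.marker_sets.values()) + list(self.signature_sets.values()):
            for g in genes:
                if g not in seen:
                    seen.add(g)
                    named.append(g)
        if len(named) > self.n_genes:
            raise ConfigError("n_genes smaller than the named gene universe")
        fillers = [f"Gene{i:04d}" for i in range(1, self.n_genes - len(named) + 1)]
        return named + fillers


@dataclass
class GroundTruthManifest:
    """Planted truth for recovery tests.

    ``cells`` has one row per simulated cell: sample, barcode, group, tissue,
    true_type, clonotype_id ('' for none), donor_compartment ('' / 'Cd4' /
    'Cd8' for macrophage TCR recipients).
    """

    cells: pd.DataFrame
    clone_sizes: Dict[str, Dict[str, int]]
    realized_trog_rate: Dict[str, float]
    sig_shift: Dict[str, float]
    seed: int

    def to_json(self, path: os.PathLike | str) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "sig_shift": self.sig_shift,
            "realized_trog_rate": self.realized_trog_rate,
            "clone_sizes": self.clone_sizes,
            "cells": self.cells.to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            cells=pd.DataFrame(payload["cells"]),
            clone_sizes=payload["clone_sizes"],
            realized_trog_rate=payload["realized_trog_rate"],
            sig_shift=payload["sig_shift"],
            seed=payload["seed"],
        )


@dataclass
class SampleData:
    sample_id: str
    group: str
    tissue: str
    matrix: ExpressionMatrix
    contigs: List[ContigRecord]
    meta: pd.DataFrame  # barcode, sample, group, tissue, true_type


@dataclass
class Cohort:
    samples: Dict[str, SampleData]
    manifest: GroundTruthManifest

    def metadata(self) -> pd.DataFrame:
        return pd.concat([s.meta for s in self.samples.values()], ignore_index=True)


def generate_clone_sizes(
    n_cells: int, dist: Dict[str, object], damp: float = 1.0, seed: int = 0
) -> List[int]:
    """Partition ``n_cells`` into clone sizes drawn from ``dist``.

    ``damp`` < 1 reduces the skew of the distribution: for a power law with
    exponent ``a`` the effective exponent is ``1 + (a - 1) / damp``; for a
    log-normal the sigma is multiplied by ``damp``.  Sizes always sum to
    ``n_cells`` exactly.
    """
    if n_cells <= 0:
        raise ConfigError("n_cells must be positive")
    if not 0.0 < damp <= 1.0:
        raise ConfigError("damp outside (0,1]")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    kind = dist.get("type")
    sizes: List[int] = []
    remaining = n_cells
    if kind == "degenerate":
        size = int(dist.get("size", 1))
        if size < 1:
            raise ConfigError("degenerate clone size must be >= 1")
        while remaining > 0:
            s = min(size, remaining)
            sizes.append(s)
            remaining -= s
    elif kind == "power_law":
        a = float(dist.get("exponent", 2.0))
        if a <= 1.0:
            raise ConfigError("power_law exponent must be > 1")
        a_eff = 1.0 + (a - 1.0) / damp
        while remaining > 0:
            s = min(int(rng.zipf(a_eff)), remaining)
            sizes.append(s)
            remaining -= s
    elif kind == "log_normal":
        mu = float(dist.get("mu", 0.0))
        sigma = float(dist.get("sigma", 1.5)) * damp
        while remaining > 0:
            s = min(max(1, int(round(rng.lognormal(mu, sigma)))), remaining)
            sizes.append(s)
            remaining -= s
    else:
        raise ConfigError(f"unknown clone-size distribution type: {kind!r}")
    assert sum(sizes) == n_cells
    return sizes


def _random_barcodes(rng: np.random.Generator, n: int) -> List[str]:
    """Unique 16-mer nucleotide barcodes with the conventional '-1' suffix."""
    bases = np.array(list("ACGT"))
    out: List[str] = []
    seen = set()
    while len(out) < n:
        bc = "".join(bases[rng.integers(0, 4, size=16)]) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _random_cdr3(rng: np.random.Generator) -> Tuple[str, str]:
    """(aa, nt) pair: 12-15 aa, C...F framing, nt length divisible by 3."""
    n_mid = int(rng.integers(10, 14))
    mid = "".join(_AA_ALPHABET[i] for i in rng.integers(0, len(_AA_ALPHABET), n_mid))
    aa = "C" + mid + "F"
    nt = "".join(_AA_CODON[c] for c in aa)
    return aa, nt


def _make_chain_pair(
    rng: np.random.Generator, clonotype_id: str
) -> List[Dict[str, str]]:
    """Chain-level identity (TRA + TRB) shared by every member of a clone."""
    chains = []
    for chain in ("TRA", "TRB"):
        aa, nt = _random_cdr3(rng)
        v = f"{chain}V{int(rng.integers(1, 21))}"
        j = f"{chain}J{int(rng.integers(1, 21))}"
        d = f"TRBD{int(rng.integers(1, 3))}" if chain == "TRB" else ""
        c = "TRBC1" if chain == "TRB" else "TRAC"
        chains.append(
            {
                "chain": chain, "v_gene": v, "d_gene": d, "j_gene": j,
                "c_gene": c, "cdr3_aa": aa, "cdr3_nt": nt,
                "clonotype_id": clonotype_id,
            }
        )
    return chains


def _contigs_for_cell(
    rng: np.random.Generator, barcode: str, chains: List[Dict[str, str]]
) -> List[ContigRecord]:
    recs = []
    for ch in chains:
        umis = int(rng.integers(2, 30))
        reads = umis * int(rng.integers(2, 10))
        recs.append(
            ContigRecord(
                barcode=barcode,
                is_cell=True,
                high_confidence=True,
                chain=ch["chain"],
                v_gene=ch["v_gene"],
                d_gene=ch["d_gene"],
                j_gene=ch["j_gene"],
                c_gene=ch["c_gene"],
                cdr3_aa=ch["cdr3_aa"],
                cdr3_nt=ch["cdr3_nt"],
                reads=reads,
                umis=umis,
                productive=True,
                raw_clonotype_id=ch["clonotype_id"],
            )
        )
    return recs


def _gene_means(cfg: CohortConfig, gene_ids: List[str]) -> np.ndarray:
    """Baseline per-gene means shared across samples.

    Named signature genes get the fixed baseline ``nb_mean`` so planted fold
    effects act on a known scale; marker genes get 4x the baseline (marker
    genes of real panels are well-detected genes); filler genes get a
    log-normal spread around the baseline so expression bins are populated.
    """
    rng = _stream_seed(cfg.seed, "gene_means")
    n_named = sum(not g.startswith("Gene") for g in gene_ids)
    means = np.empty(len(gene_ids))
    means[:n_named] = cfg.nb_mean
    marker_genes = {g for genes in cfg.marker_sets.values() for g in genes}
    for i in range(n_named):
        if gene_ids[i] in marker_genes:
            means[i] = cfg.nb_mean * 4.0
    means[n_named:] = cfg.nb_mean * rng.lognormal(0.0, 1.2, size=len(gene_ids) - n_named)
    return means


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate the full paired cohort.  Deterministic given ``cfg.seed``."""
    cfg.validate()
    gene_ids = cfg.gene_universe()
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    base_means = _gene_means(cfg, gene_ids)
    props = cfg.proportions()
    cell_types = sorted({t for p in props.values() for t in p})

    # genes x types multiplier for marker elevation
    type_mult = np.ones((len(gene_ids), len(cell_types)))
    for j, ct in enumerate(cell_types):
        for g in cfg.marker_sets.get(ct, []):
            if g in gene_index:
                type_mult[gene_index[g], j] = cfg.marker_fold

    samples: Dict[str, SampleData] = {}
    all_cells: List[Dict[str, object]] = []
    clone_size_tables: Dict[str, Dict[str, int]] = {}
    trog_counts = {t: [0, 0] for t in cfg.tissues}  # tissue -> [n_trog, n_mac]

    for group in GROUPS:
        for tissue in cfg.tissues:
            for rep in range(1, cfg.n_samples_per_arm + 1):
                sid = f"{group}_{tissue}_{rep}"
                rng = _stream_seed(cfg.seed, f"sample:{sid}")
                p = props[(tissue, group)]
                type_probs = np.array([p.get(ct, 0.0) for ct in cell_types])
                type_idx = rng.choice(len(cell_types), size=cfg.n_cells_per_sample,
                                      p=type_probs)
                barcodes = _random_barcodes(rng, cfg.n_cells_per_sample)
                types = [cell_types[i] for i in type_idx]

                # per-sample signature shift vector
                shift = np.ones(len(gene_ids))
                for (set_id, g_grp, g_tis), delta in cfg.sig_shift.items():
                    if g_grp == group and g_tis == tissue:
                        for g in cfg.signature_sets.get(set_id, []):
                            if g in gene_index:
                                shift[gene_index[g]] *= np.exp(delta)

                mean_mat = (base_means * shift)[:, None] * type_mult[:, type_idx]
                r = cfg.nb_dispersion
                lam = rng.gamma(shape=r, scale=mean_mat / r)
                counts = rng.poisson(lam).astype(np.int64)
                matrix = ExpressionMatrix(
                    gene_ids=list(gene_ids),
                    barcodes=list(barcodes),
                    counts=sp.csr_matrix(counts),
                )

                damp = cfg.expansion_damp if group == "sephin1" else 1.0
                contigs: List[ContigRecord] = []
                cell_clonotype = {bc: "" for bc in barcodes}
                cell_chains: Dict[str, List[Dict[str, str]]] = {}
                sizes_table: Dict[str, int] = {}
                compartment_cells: Dict[str, List[str]] = {"Cd4": [], "Cd8": []}

                clone_counter = 0
                for ct, comp in (("Cd4_T", "Cd4"), ("Cd8_T", "Cd8"), ("NKT", None)):
                    members = [bc for bc, t in zip(barcodes, types) if t == ct]
                    if not members:
                        continue
                    sizes = generate_clone_sizes(
                        len(members), cfg.clone_dist, damp,
                        seed=_stream_seed(cfg.seed, f"clones:{sid}:{ct}"),
                    )
                    order = rng.permutation(len(members))
                    pos = 0
                    for size in sizes:
                        clone_counter += 1
                        cid = f"{sid}_clonotype{clone_counter}"
                        chains = _make_chain_pair(rng, cid)
                        sizes_table[cid] = size
                        for k in range(size):
                            bc = members[order[pos + k]]
                            cell_clonotype[bc] = cid
                            cell_chains[bc] = chains
                            contigs.extend(_contigs_for_cell(rng, bc, chains))
                            if comp is not None:
                                compartment_cells[comp].append(bc)
                        pos += size

                # trogocytosis: macrophages receive a donor T cell's contigs
                donor_compartment = {bc: "" for bc in barcodes}
                rate = cfg.trog_rate.get(tissue, 0.0)
                macs = [bc for bc, t in zip(barcodes, types) if t == "Macrophage"]
                trog_counts[tissue][1] += len(macs)
                for bc in macs:
                    if rate <= 0.0 or rng.random() >= rate:
                        continue
                    comp = "Cd8" if rng.random() < cfg.trog_donor_mix else "Cd4"
                    if not compartment_cells[comp]:
                        comp = "Cd4" if comp == "Cd8" else "Cd8"
                    if not compartment_cells[comp]:
                        continue
                    donors = compartment_cells[comp]
                    donor_bc = donors[int(rng.integers(0, len(donors)))]
                    donor_compartment[bc] = comp
                    cell_clonotype[bc] = cell_clonotype[donor_bc]
                    contigs.extend(
                        _contigs_for_cell(rng, bc, cell_chains[donor_bc])
                    )
                    trog_counts[tissue][0] += 1

                meta = pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "sample": sid,
                        "group": group,
                        "tissue": tissue,
                        "true_type": types,
                        "clonotype_id": [cell_clonotype[bc] for bc in barcodes],
                        "donor_compartment": [donor_compartment[bc] for bc in barcodes],
                    }
                )
                samples[sid] = SampleData(
                    sample_id=sid, group=group, tissue=tissue,
                    matrix=matrix, contigs=contigs, meta=meta,
                )
                clone_size_tables[sid] = sizes_table
                all_cells.append(meta)

    manifest = GroundTruthManifest(
        cells=pd.concat(all_cells, ignore_index=True),
        clone_sizes=clone_size_tables,
        realized_trog_rate={
            t: (c[0] / c[1] if c[1] else float("nan")) for t, c in trog_counts.items()
        },
        sig_shift={f"{k[0]}|{k[1]}|{k[2]}": v for k, v in cfg.sig_shift.items()},
        seed=cfg.seed,
    )
    return Cohort(samples=samples, manifest=manifest)


def write_cohort(cohort: Cohort, out_dir: os.PathLike | str) -> Path:
    """Emit the cohort in the io_tenx formats plus metadata TSV and manifest."""
    out_dir = Path(out_dir)
    for sid, sample in cohort.samples.items():
        sdir = out_dir / "samples" / sid
        write_matrix(sample.matrix, sdir)
        write_contigs(sample.contigs, sdir / "filtered_contig_annotations.csv")
    meta = cohort.metadata()
    meta.to_csv(out_dir / "cell_metadata.tsv", sep="\t", index=False)
    cohort.manifest.to_json(out_dir / "ground_truth.json")
    return out_dir
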