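"""Expression-bin-matched gene-set scoring and the M1-to-M2 polarization score.

The module score of a gene set is the per-cell mean log-normalised expression
of the set genes minus the mean over pooled control draws, where each set
gene contributes ``n_ctrl`` control genes drawn uniformly with replacement
from its expression bin (genes ranked by mean expression across cells, cut
into ``n_bins`` equal-size bins).  Defaults (24 bins, 100 controls) mirror
the conventional implementation of this scheme.

Control draws are seeded per (seed, gene-set content, set gene identity), so
scores are invariant to gene row order and to gene-set argument position, and
the M1 and M2 scores use independent but reproducible draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_tenx import ExpressionMatrix
from .qc import log_normalize
from .stats import holm_adjust, wilcoxon_rank_sum

__all__ = ["SignatureResult", "module_score", "m1_to_m2", "score_group_contrast"]


@dataclass
class SignatureResult:
    gene_set_id: str
    barcodes: List[str]
    scores: np.ndarray
    params: Dict[str, object]

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.barcodes, name=self.gene_set_id)


def _hash64(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big")


def _set_identity(gene_set_id: Optional[str], genes: Sequence[str]) -> str:
    if gene_set_id is not None:
        return gene_set_id
    return hashlib.sha256("|".join(sorted(genes)).encode()).hexdigest()[:12]


def _expression_bins(
    x: np.ndarray, gene_ids: Sequence[str], n_bins: int
) -> Dict[str, List[str]]:
    """Gene -> sorted member list of its expression bin.

    Genes are ordered by (mean expression, gene id) — the id tiebreak makes
    binning independent of row order — and split into ``n_bins`` nearly
    equal-size bins.
    """
    avg = x.mean(axis=1)
    order = sorted(range(len(gene_ids)), key=lambda i: (avg[i], gene_ids[i]))
    bins = np.array_split(order, n_bins)
    gene_to_members: Dict[str, List[str]] = {}
    for b in bins:
        members = sorted(gene_ids[i] for i in b)
        for i in b:
            gene_to_members[gene_ids[i]] = members
    return gene_to_members


def module_score(
    m: ExpressionMatrix,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    gene_set_id: Optional[str] = None,
    normalize: bool = True,
) -> SignatureResult:
    """Bin-matched control score; see the module docstring for the scheme.

    Set genes absent from the matrix are dropped; an entirely absent set
    raises :class:`ConfigError` naming the missing symbols.  With
    ``normalize=False`` the counts are treated as already log-scale.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ConfigError("n_bins and n_ctrl must be >= 1")
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    present = [g for g in gene_set if g in gene_index]
    missing = [g for g in gene_set if g not in gene_index]
    if not present:
        raise ConfigError(f"no gene of the set is present in the matrix: {missing}")

    x = log_normalize(m) if normalize else np.asarray(m.counts.todense(), dtype=float)
    bins = _expression_bins(x, m.gene_ids, n_bins)
    set_id = _set_identity(gene_set_id, gene_set)

    set_rows = [gene_index[g] for g in present]
    set_mean = x[set_rows, :].mean(axis=0)

    ctrl_sum = np.zeros(m.n_cells)
    n_draws = 0
    for g in sorted(present):
        members = bins[g]
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), _hash64(set_id), _hash64(g)])
        )
        draws = rng.integers(0, len(members), size=n_ctrl)
        rows = [gene_index[members[d]] for d in draws]
        ctrl_sum += x[rows, :].sum(axis=0)
        n_draws += n_ctrl
    ctrl_mean = ctrl_sum / n_draws

    return SignatureResult(
        gene_set_id=set_id,
        barcodes=list(m.barcodes),
        scores=set_mean - ctrl_mean,
        params={
            "n_bins": n_bins,
            "n_ctrl": n_ctrl,
            "seed": seed,
            "normalization": "per10k_log1p" if normalize else "pre_normalized",
            "missing_genes": missing,
        },
    )


def m1_to_m2(
    m: ExpressionMatrix,
    m1_set: Sequence[str],
    m2_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SignatureResult:
    """M1 module score minus M2 module score; higher means more M1-polarised.

    Both scores use the same seed policy (keyed by set content), so
    ``m1_to_m2(A, B) == -m1_to_m2(B, A)`` exactly.
    """
    s1 = module_score(m, m1_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    s2 = module_score(m, m2_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    return SignatureResult(
        gene_set_id=f"{s1.gene_set_id}_minus_{s2.gene_set_id}",
        barcodes=list(m.barcodes),
        scores=s1.scores - s2.scores,
        params={**s1.params, "difference_of": [s1.gene_set_id, s2.gene_set_id]},
    )


def score_group_contrast(
    scores: pd.Series,
    meta: pd.DataFrame,
    strata: Sequence[str] = ("blood_d0", "blood_d15", "tumor_d15"),
    group_col: str = "group",
    tissue_col: str = "tissue",
    groups: Tuple[str, str] = ("normal", "sephin1"),
) -> pd.DataFrame:
    """Per-stratum Wilcoxon rank-sum between the two arms, Holm-adjusted
    across strata.

    ``scores`` is indexed by barcode; ``meta`` carries barcode, group and
    tissue columns.  Direction is the sign of median(second arm) minus
    median(first arm).  Degenerate strata (< 2 cells in either arm) are
    reported as not testable and excluded from the adjustment.
    """
    meta = meta.set_index("barcode") if "barcode" in meta.columns else meta
    rows = []
    pvals, testable_idx = [], []
    for i, stratum in enumerate(strata):
        sel = meta[tissue_col] == stratum
        idx = meta.index[sel].intersection(scores.index)
        sub = meta.loc[idx]
        x = scores.loc[sub.index[sub[group_col] == groups[0]]].to_numpy()
        y = scores.loc[sub.index[sub[group_col] == groups[1]]].to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append(
                {"stratum": stratum, "n_a": len(x), "n_b": len(y),
                 "direction": np.nan, "p": np.nan, "p_adj": np.nan,
                 "testable": False}
            )
            continue
        res = wilcoxon_rank_sum(x, y)
        rows.append(
            {"stratum": stratum, "n_a": len(x), "n_b": len(y),
             "direction": float(np.sign(np.median(y) - np.median(x))),
             "p": res.p, "p_adj": np.nan, "testable": True}
        )
        pvals.append(res.p)
        testable_idx.append(len(rows) - 1)
    if pvals:
        adj = holm_adjust(pvals)
        for j, i in enumerate(testable_idx):
            rows[i]["p_adj"] = adj[j]
    return pd.DataFrame(rows)
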