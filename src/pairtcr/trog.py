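"""TCR-bearing macrophage detection and clonotype sharing with T cells.

A cell is TCR+ iff its barcode owns at least one retained clonotype in its
own sample's clonotype table (barcodes never match across samples).  Among
TCR+ macrophages, the Cd8-share (Cd4-share) is the fraction whose clonotype
key set intersects the Cd8+ (Cd4+) T-cell clonotype set of the same sample;
macrophages shared with both compartments count in both and are also
reported separately.  All quantities are computed per sample and aggregated
per (tissue, group) stratum; pooled outputs are emitted alongside.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .repertoire import BIN_LABELS, ClonotypeTable

__all__ = [
    "match_barcodes",
    "tcr_mac_fraction",
    "shared_clonotype_fractions",
    "tcr_mac_bin_distribution",
]

logger = logging.getLogger(__name__)


def _require_columns(meta: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = set(cols) - set(meta.columns)
    if missing:
        raise ConfigError(f"metadata lacks columns: {sorted(missing)}")


def match_barcodes(
    meta: pd.DataFrame, tables: Mapping[str, ClonotypeTable]
) -> pd.Series:
    """Boolean TCR+ flag per metadata row, matched within sample only."""
    _require_columns(meta, ["barcode", "sample"])
    owners: Dict[str, set] = {
        sid: set(t.barcode_to_key()) for sid, t in tables.items()
    }
    flags = [
        row.barcode in owners.get(row.sample, set())
        for row in meta.itertuples(index=False)
    ]
    return pd.Series(flags, index=meta.index, name="tcr_positive")


def tcr_mac_fraction(
    meta: pd.DataFrame,
    flags: pd.Series,
    cell_type_col: str = "cell_type",
    macrophage_label: str = "Macrophage",
) -> pd.DataFrame:
    """TCR+ macrophages over all macrophages per (tissue, group).

    Strata with zero macrophages get a NaN fraction (undefined, not zero).
    """
    _require_columns(meta, ["tissue", "group", cell_type_col])
    df = meta.assign(tcr_positive=flags.to_numpy())
    macs = df[df[cell_type_col] == macrophage_label]
    rows = []
    for (tissue, group), sub in macs.groupby(["tissue", "group"], sort=True):
        n = len(sub)
        k = int(sub["tcr_positive"].sum())
        rows.append(
            {
                "tissue": tissue,
                "group": group,
                "n_macrophages": n,
                "n_tcr_pos_macrophages": k,
                "tcr_mac_fraction": k / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def shared_clonotype_fractions(
    meta: pd.DataFrame,
    tables: Mapping[str, ClonotypeTable],
    cell_type_col: str = "cell_type",
    macrophage_label: str = "Macrophage",
    cd4_label: str = "Cd4_T",
    cd8_label: str = "Cd8_T",
) -> pd.DataFrame:
    """Cd4-/Cd8-share of TCR+ macrophages per (tissue, group).

    Shares are fractions of TCR+ macrophages whose clonotype key set
    intersects the same sample's Cd4+/Cd8+ T-cell clonotype sets; dual-shared
    macrophages count in both shares and are reported in ``dual_share``.
    Strata with no TCR+ macrophages report NaN shares.
    """
    _require_columns(meta, ["barcode", "sample", "tissue", "group", cell_type_col])
    per_sample = []
    for sid, table in tables.items():
        sub = meta[meta["sample"] == sid]
        if sub.empty:
            continue
        bc2key = table.barcode_to_key()
        cd4_keys = {
            bc2key[b]
            for b in sub.loc[sub[cell_type_col] == cd4_label, "barcode"]
            if b in bc2key
        }
        cd8_keys = {
            bc2key[b]
            for b in sub.loc[sub[cell_type_col] == cd8_label, "barcode"]
            if b in bc2key
        }
        mac_bcs = [
            b
            for b in sub.loc[sub[cell_type_col] == macrophage_label, "barcode"]
            if b in bc2key
        ]
        n_cd4 = n_cd8 = n_dual = 0
        for b in mac_bcs:
            in4 = bc2key[b] in cd4_keys
            in8 = bc2key[b] in cd8_keys
            n_cd4 += in4
            n_cd8 += in8
            n_dual += in4 and in8
        per_sample.append(
            {
                "sample": sid,
                "tissue": sub["tissue"].iloc[0],
                "group": sub["group"].iloc[0],
                "n_tcr_pos_macrophages": len(mac_bcs),
                "n_cd4_shared": n_cd4,
                "n_cd8_shared": n_cd8,
                "n_dual_shared": n_dual,
            }
        )
    if not per_sample:
        return pd.DataFrame(
            columns=["tissue", "group", "n_tcr_pos_macrophages", "n_cd4_shared",
                     "n_cd8_shared", "n_dual_shared", "cd4_share", "cd8_share",
                     "dual_share"]
        )
    df = pd.DataFrame(per_sample)
    agg = (
        df.groupby(["tissue", "group"], sort=True)[
            ["n_tcr_pos_macrophages", "n_cd4_shared", "n_cd8_shared", "n_dual_shared"]
        ]
        .sum()
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = agg["n_tcr_pos_macrophages"].to_numpy(dtype=float)
        denom_safe = np.where(denom > 0, denom, np.nan)
        agg["cd4_share"] = agg["n_cd4_shared"] / denom_safe
        agg["cd8_share"] = agg["n_cd8_shared"] / denom_safe
        agg["dual_share"] = agg["n_dual_shared"] / denom_safe
    return agg


def tcr_mac_bin_distribution(
    meta: pd.DataFrame,
    flags: pd.Series,
    bin_labels: Mapping[str, str],
    cell_type_col: str = "cell_type",
    macrophage_label: str = "Macrophage",
) -> pd.DataFrame:
    """Expansion-bin shares among TCR+ macrophages per (tissue, group).

    ``bin_labels`` maps barcode -> bin (from ``cell_bin_labels``).  Shares
    sum to 1 per stratum; empty strata are omitted with a warning.
    """
    _require_columns(meta, ["barcode", "tissue", "group", cell_type_col])
    df = meta.assign(tcr_positive=flags.to_numpy())
    macs = df[(df[cell_type_col] == macrophage_label) & df["tcr_positive"]]
    rows = {}
    for (tissue, group), sub in macs.groupby(["tissue", "group"], sort=True):
        counts = {b: 0 for b in BIN_LABELS}
        for bc in sub["barcode"]:
            label = bin_labels.get(bc, "none")
            if label in counts:
                counts[label] += 1
        total = sum(counts.values())
        if total == 0:
            logger.warning(
                "tcr_mac_bin_distribution: stratum (%s, %s) empty; omitted",
                tissue, group,
            )
            continue
        rows[(tissue, group)] = {b: counts[b] / total for b in BIN_LABELS}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(BIN_LABELS))
    if len(out):
        out.index = pd.MultiIndex.from_tuples(out.index, names=["tissue", "group"])
    return out
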