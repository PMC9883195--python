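"""End-to-end orchestration: generate/ingest -> QC -> annotate -> repertoire
-> signatures -> trogocytosis -> statistics, with a reproducible report
bundle.

Every stage logs counts in/out; a stage failure halts the run with an error
naming the stage, leaves partial outputs in place, and drops a ``FAILED``
marker file.  Given fixed seeds, two runs produce byte-identical bundles (no
timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .defaults import DEFAULT_MARKER_SETS, DEFAULT_SIGNATURE_SETS, TISSUE_DISPLAY
from .errors import ConfigError, StageError
from .io_tenx import concat_cells, read_contigs, read_matrix
from .qc import assign_cell_types, composition_table, qc_filter
from .repertoire import (
    BinThresholds,
    bin_clonotypes,
    bin_composition,
    call_clonotypes,
    cell_bin_labels,
    compute_frequencies,
)
from .signatures import m1_to_m2, module_score, score_group_contrast
from .stats import chi_squared_composition, stars
from .synthetic import Cohort, CohortConfig, generate_cohort, write_cohort
from .trog import (
    match_barcodes,
    shared_clonotype_fractions,
    tcr_mac_bin_distribution,
    tcr_mac_fraction,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "directory"
    out_dir: str = "pairtcr_run"
    input_dir: Optional[str] = None  # directory mode: cohort root
    seed: int = 0
    qc_min_cells_per_gene: int = 2
    qc_min_genes: int = 100
    qc_max_genes: int = 4000
    qc_mito_max: Optional[float] = None
    clonotype_strategy: str = "nt+gene"
    bin_thresholds: BinThresholds = field(default_factory=BinThresholds)
    marker_sets: Dict[str, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_SETS.items()}
    )
    signature_sets: Dict[str, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURE_SETS.items()}
    )
    use_provided_labels: bool = False
    synthetic: Optional[CohortConfig] = None

    def resolved_synthetic(self) -> CohortConfig:
        cfg = self.synthetic if self.synthetic is not None else CohortConfig()
        return dataclasses.replace(cfg, seed=self.seed)


def _load_directory_cohort(root: Path) -> Tuple[Dict[str, dict], pd.DataFrame]:
    meta_path = root / "cell_metadata.tsv"
    if not meta_path.exists():
        raise ConfigError(f"directory mode requires {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    samples = {}
    for sid in sorted(meta["sample"].unique()):
        sdir = root / "samples" / sid
        contig_path = sdir / "filtered_contig_annotations.csv"
        if not contig_path.exists():
            raise StageError("ingest", f"sample {sid} is missing its contig CSV")
        samples[sid] = {
            "matrix": read_matrix(sdir),
            "contigs": read_contigs(contig_path),
            "meta": meta[meta["sample"] == sid].reset_index(drop=True),
        }
    return samples, meta


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full chain and write the report bundle; returns the out dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        return _run(cfg, out)
    except Exception as exc:
        failed_marker.write_text(str(exc))
        if isinstance(exc, StageError):
            raise
        raise StageError("pipeline", str(exc)) from exc


def _run(cfg: RunConfig, out: Path) -> Path:
    # ---- stage: acquire ---------------------------------------------------
    stage = "acquire"
    try:
        if cfg.mode == "synthetic":
            cohort = generate_cohort(cfg.resolved_synthetic())
            write_cohort(cohort, out / "inputs")
            samples = {
                sid: {"matrix": s.matrix, "contigs": s.contigs, "meta": s.meta}
                for sid, s in cohort.samples.items()
            }
            meta_all = cohort.metadata()
        elif cfg.mode == "directory":
            if cfg.input_dir is None:
                raise ConfigError("directory mode requires input_dir")
            samples, meta_all = _load_directory_cohort(Path(cfg.input_dir))
        else:
            raise ConfigError(f"unknown mode '{cfg.mode}'")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: qc + annotate --------------------------------------------
    stage = "qc_annotation"
    try:
        cell_meta_rows = []
        qc_log = {}
        matrices = {}
        for sid in sorted(samples):
            s = samples[sid]
            m, report = qc_filter(
                s["matrix"],
                min_cells_per_gene=cfg.qc_min_cells_per_gene,
                min_genes_exclusive=cfg.qc_min_genes,
                max_genes_exclusive=cfg.qc_max_genes,
                mito_max=cfg.qc_mito_max,
                return_report=True,
            )
            matrices[sid] = m
            qc_log[sid] = dataclasses.asdict(report)
            smeta = s["meta"].set_index("barcode")
            kept = smeta.loc[[b for b in m.barcodes if b in smeta.index]]
            if cfg.use_provided_labels and "cell_type" in kept.columns:
                labels = kept["cell_type"].tolist()
            elif cfg.use_provided_labels and "true_type" in kept.columns:
                labels = kept["true_type"].tolist()
            else:
                labels = assign_cell_types(m, cfg.marker_sets)
            df = kept.reset_index()
            df["cell_type"] = labels
            cell_meta_rows.append(df)
        meta = pd.concat(cell_meta_rows, ignore_index=True)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: composition ----------------------------------------------
    stage = "composition"
    try:
        comp = composition_table(meta)
        comp_out = comp.rename(index=TISSUE_DISPLAY, level=0)
        _write_csv(comp_out, out / "composition.csv", index=True)
        comp_tests = []
        for tissue in sorted(meta["tissue"].unique()):
            sub = meta[meta["tissue"] == tissue]
            tab = pd.crosstab(sub["group"], sub["cell_type"])
            if tab.shape[0] == 2 and tab.shape[1] >= 2:
                res = chi_squared_composition(tab.to_numpy())
                comp_tests.append(
                    {"contrast": "composition", "stratum": tissue,
                     "statistic": res.statistic, "p": res.p,
                     "p_adj": np.nan, "stars": stars(res.p)}
                )
        _write_csv(pd.DataFrame(comp_tests), out / "composition_tests.csv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: repertoire ------------------------------------------------
    stage = "repertoire"
    try:
        tables = {}
        for sid in sorted(samples):
            t = call_clonotypes(samples[sid]["contigs"], sample_id=sid,
                                strategy=cfg.clonotype_strategy)
            tables[sid] = bin_clonotypes(compute_frequencies(t), cfg.bin_thresholds)
        clono_frames = [tables[sid].to_frame() for sid in sorted(tables)]
        _write_csv(pd.concat(clono_frames, ignore_index=True),
                   out / "clonotype_tables.csv")
        sample_strata = {
            sid: (samples[sid]["meta"]["tissue"].iloc[0],
                  samples[sid]["meta"]["group"].iloc[0])
            for sid in samples
        }
        clono_comp, cell_comp = bin_composition(tables, sample_strata)
        _write_csv(clono_comp, out / "clonotype_bins_clonotype_level.csv", index=True)
        _write_csv(cell_comp, out / "clonotype_bins_cell_level.csv", index=True)

        bin_by_barcode: Dict[str, str] = {}
        for sid in sorted(samples):
            sub = meta[meta["sample"] == sid]
            bin_by_barcode.update(cell_bin_labels(tables[sid], sub["barcode"]))
        meta["expansion_bin"] = [
            bin_by_barcode.get(bc, "none") for bc in meta["barcode"]
        ]

        # T-cell level bin contrast per tissue (cell-level counts)
        bin_tests = []
        tcr_cells = meta[meta["expansion_bin"] != "none"]
        for tissue in sorted(tcr_cells["tissue"].unique()):
            sub = tcr_cells[tcr_cells["tissue"] == tissue]
            tab = pd.crosstab(sub["group"], sub["expansion_bin"])
            if tab.shape[0] == 2 and tab.shape[1] >= 2:
                res = chi_squared_composition(tab.to_numpy())
                bin_tests.append(
                    {"contrast": "cell_bin_distribution", "stratum": tissue,
                     "statistic": res.statistic, "p": res.p,
                     "p_adj": np.nan, "stars": stars(res.p)}
                )
        _write_csv(pd.DataFrame(bin_tests), out / "clonotype_bin_tests.csv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: signatures ------------------------------------------------
    stage = "signatures"
    try:
        score_rows = []
        contrast_frames = []

        def _score_subset(cell_type: str, kind: str, set_id) -> None:
            # pool the contrasted cells across samples before scoring:
            # bin-matched controls computed per sample would absorb any
            # between-arm shift by construction
            sel = meta[meta["cell_type"] == cell_type]
            if sel.empty:
                return
            subs, keys = [], []
            for sid in sorted(samples):
                m = matrices[sid]
                wanted = set(sel.loc[sel["sample"] == sid, "barcode"])
                cols = [i for i, b in enumerate(m.barcodes) if b in wanted]
                if not cols:
                    continue
                subs.append(m.subset_cells(cols))
                keys.append(sid)
            if not subs or sum(s.n_cells for s in subs) < 4:
                return
            # per-sample QC can drop different genes; pool on the intersection
            common = set(subs[0].gene_ids)
            for s in subs[1:]:
                common &= set(s.gene_ids)
            subs = [
                s.subset_genes([i for i, g in enumerate(s.gene_ids) if g in common])
                for s in subs
            ]
            pooled = concat_cells(subs, barcode_prefixes=keys)
            if kind == "m1_to_m2":
                res = m1_to_m2(pooled, cfg.signature_sets["M1"],
                               cfg.signature_sets["M2"], seed=cfg.seed)
                label = "M1_to_M2"
            else:
                res = module_score(pooled, cfg.signature_sets[set_id],
                                   seed=cfg.seed, gene_set_id=set_id)
                label = set_id
            for key, sc in zip(res.barcodes, res.scores):
                sid, bc = key.split(":", 1)
                score_rows.append(
                    {"barcode": bc, "sample": sid, "cell_type": cell_type,
                     "signature": label, "score": sc}
                )

        if "cytotoxicity" in cfg.signature_sets:
            _score_subset("Cd8_T", "module", "cytotoxicity")
        if "M1" in cfg.signature_sets and "M2" in cfg.signature_sets:
            _score_subset("Macrophage", "m1_to_m2", None)

        scores_df = pd.DataFrame(
            score_rows, columns=["barcode", "sample", "cell_type", "signature", "score"]
        )
        _write_csv(scores_df, out / "signature_scores.csv")
        meta_keyed = meta.assign(cellkey=meta["sample"] + ":" + meta["barcode"])
        meta_keyed = meta_keyed.set_index("cellkey")[["group", "tissue"]]
        for signature in sorted(scores_df["signature"].unique()):
            sdf = scores_df[scores_df["signature"] == signature]
            series = pd.Series(
                sdf["score"].to_numpy(),
                index=(sdf["sample"] + ":" + sdf["barcode"]).to_numpy(),
            )
            contrast = score_group_contrast(series, meta_keyed)
            contrast.insert(0, "signature", signature)
            contrast["stars"] = [
                stars(p) if np.isfinite(p) else "ns" for p in contrast["p_adj"]
            ]
            contrast_frames.append(contrast)
        if contrast_frames:
            _write_csv(pd.concat(contrast_frames, ignore_index=True),
                       out / "signature_contrasts.csv")
        else:
            _write_csv(pd.DataFrame(), out / "signature_contrasts.csv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: trogocytosis ----------------------------------------------
    stage = "trogocytosis"
    try:
        flags = match_barcodes(meta, tables)
        meta["tcr_positive"] = flags.to_numpy()
        frac = tcr_mac_fraction(meta, flags)
        _write_csv(frac, out / "tcr_mac_fractions.csv")
        shares = shared_clonotype_fractions(meta, tables)
        _write_csv(shares, out / "tcr_mac_shares.csv")
        bins = tcr_mac_bin_distribution(meta, flags, bin_by_barcode)
        _write_csv(bins, out / "tcr_mac_bin_distribution.csv", index=True)
        report = {
            "fractions": frac.to_dict(orient="records"),
            "shares": shares.to_dict(orient="records"),
        }
        (out / "tcr_mac_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, allow_nan=True)
        )
        _write_csv(meta, out / "cell_table.csv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: manifest --------------------------------------------------
    manifest = {
        "pairtcr_version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "qc": {
            "min_cells_per_gene": cfg.qc_min_cells_per_gene,
            "min_genes_exclusive": cfg.qc_min_genes,
            "max_genes_exclusive": cfg.qc_max_genes,
            "mito_max": cfg.qc_mito_max,
            "per_sample": qc_log,
        },
        "clonotype_strategy": cfg.clonotype_strategy,
        "bin_thresholds": dataclasses.asdict(cfg.bin_thresholds),
        "marker_sets": cfg.marker_sets,
        "signature_sets": cfg.signature_sets,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return out
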