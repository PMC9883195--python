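# pairtcr

Analysis pipeline for paired single-cell gene-expression (GEX) and
TCR-enrichment (VDJ) libraries:

- **io_tenx** — MatrixMarket count-matrix directories (with feature/barcode
  sidecars, gzip-transparent) and the `filtered_contig_annotations.csv`
  contig dialect, read and written bit-faithfully.
- **synthetic** — a paired GEX+VDJ cohort simulator with planted,
  recoverable ground truth: negative-binomial counts with cell-type marker
  elevation, group/tissue signature shifts, skewed clone-size distributions
  with dampable expansion in the treated arm, and a configurable rate of
  TCR transfer from T cells to macrophages.
- **qc** — the stated QC filters (genes in ≥2 cells; cells with >100 and
  <4000 detected genes, strict by default) and marker-score cell typing.
- **repertoire** — clonotype calling from contigs (per-barcode top-UMI
  chain selection, nt+gene or aa keys), frequency computation, expansion
  binning (hyperexpanded/large/medium/small (+rare) on half-open (lo, hi]
  intervals), ranking, and per-stratum bin composition.
- **signatures** — expression-bin-matched module scores (24 bins, 100
  seeded control draws per set gene) and the M1_to_M2 polarization score
  (M1 score − M2 score), with Wilcoxon + Holm group contrasts.
- **trog** — TCR-bearing macrophage detection by within-sample GEX/VDJ
  barcode intersection, per-stratum fractions, expansion-bin distribution,
  and Cd4-/Cd8-share of clonotypes with T-cell compartments.
- **stats** — chi-squared homogeneity on raw counts, exact/asymptotic
  Wilcoxon rank-sum, unpaired t-test, Bonferroni–Holm, significance stars,
  regulon specificity score (1 − √JSD, base-2), and the caliper tumor
  volume V = d²·D/2.
- **pipeline / cli** — one reproducible run from config + seed to a CSV/JSON
  report bundle (byte-identical across reruns with the same seed).

## CLI

```bash
# synthetic cohort with planted ground truth
pairtcr simulate --seed 1 --out cohort/

# full pipeline (synthetic mode, or --mode directory --input-dir cohort/)
pairtcr run --seed 1 --out run1/

# pieces
pairtcr repertoire cohort/samples/<sid>/filtered_contig_annotations.csv --out clonotypes.csv
pairtcr score cohort/samples/<sid> --genes Gzmb,Prf1,Ifng --out scores.csv
pairtcr stats --test chi2 --table counts.csv
pairtcr stats --test volume --d 2 --big-d 4
```

YAML configs can override any `RunConfig`/`CohortConfig` field
(`pairtcr run --config run.yaml ...`, with synthetic-cohort parameters under
a `synthetic:` key).

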