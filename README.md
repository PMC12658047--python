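# presig

Presymptomatic blood-transcriptome screening pipeline for case/control UMI
RNA-seq count matrices with ERCC-style spike-ins, plus a synthetic-data
generator with full ground truth so every stage is testable offline.

Stages:

1. **QC / cohort** — IQR-based outlier exclusion on six per-sample QC
   metrics; cohort comparison table (Shapiro-Wilk-gated Welch t-test vs
   Mann-Whitney U, chi-square with Yates correction for categoricals).
2. **Normalization / bias** — low-count filtering (spike-ins exempt),
   median-of-ratios size factors anchored on non-zero spike-ins, offset+log2
   transform, and per-gene negative-binomial library-bias correction
   (2 libraries, corrected counts stay integral).
3. **Feature selection** — spike-in-anchored fluctuation test: per-gene CV²
   vs the technical curve `CV²(µ) = a1/µ + α0` fitted on spike-ins,
   chi-square upper-tail test, BH; spike-ins are always retained.
4. **PCA / phenotype** — bottom-20%-variance trim, centred+scaled SVD PCA
   with a fixed sign convention, Pearson/point-biserial PC–covariate
   correlations, selection of condition-correlated PCs (|r| ≥ 0.25).
5. **GSEA** — preranked weighted-KS enrichment on PC loadings with a
   gene-sampling null, NES, permutation p (add-one smoothing, adaptive
   escalation), BH, leading-edge genes, and the direction-of-change rule
   `sign(NES) × sign(r) > 0 ⇒ upregulated in cases`; Z-score heatmap
   matrices ordered by loadings/scores.
6. **DGE** — simplified per-gene NB Wald test (condition covariate, log
   size-factor offset, Cox-Reid ML dispersion with a trend fallback), BH.
7. **Biomarker screen** — per-variable logistic orientation + ROC: AUC with
   DeLong CI and one-sided Mann-Whitney p, sensitivity/specificity/accuracy
   at a fixed 10% FPR with stratified-bootstrap CIs, strict
   sensitivity > 0.65 candidate filter, two-sided Wilcoxon group test.
8. **Cell types** — one-vs-rest marker derivation from a labelled reference
   (log2FC > 2.32, padj < 0.05, progenitor-label blacklist), GMT export,
   and marker-set enrichment in AUC-/sensitivity-ranked biomarkers.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact oracle
equivalence for ES/AUC/operating point, calibration and power simulations,
end-to-end planted-pathway recovery over 20 seeds, and more). The whole
suite runs in a few minutes on one CPU.

## CLI

One subcommand per stage; stages exchange plain-text files through
`--out-dir`:

```bash
presig simulate --n-genes 12000 --n-spikeins 97 \
    --pathway UP1:30:1.0 --pathway DOWN1:30:-1.0 --biomarker 1.6 \
    --seed 1 --out-dir run1
presig qc        --out-dir run1
presig normalize --out-dir run1
presig select    --out-dir run1
presig pca       --out-dir run1
presig gsea      --gmt run1/gene_sets.gmt --out-dir run1
presig dge       --out-dir run1
presig screen    --out-dir run1
presig celltype  --out-dir run1
```

or everything at once (simulating a study if `counts.tsv` is absent):

```bash
presig run-all --seed 1 --out-dir run1
```

All thresholds are flags with the pipeline defaults; a YAML `--config` file
can override simulation parameters. Exit code 2 signals a validation error.

To analyse real data instead, place `counts.tsv` (genes × samples TSV,
`ERCC-`-prefixed spike-in rows), `metadata.csv` (with `condition` PE/NP and
`library` columns) and `qc.csv` in the output directory and skip `simulate`.

## Python API

```python
from presig import SimulationConfig, PlantedPathway, generate_dataset
from presig.pipeline import run_pipeline
from presig.simulate import simulate_qc_table

cfg = SimulationConfig(planted_pathways=(PlantedPathway("UP1", 30, 1.0),), seed=1)
counts, meta, gene_sets, truth = generate_dataset(cfg)
result = run_pipeline(counts, meta, gene_sets=gene_sets,
                      qc_table=simulate_qc_table(counts, seed=1), seed=1)
result.pc_correlation.selected      # condition-correlated PCs
result.gsea_by_pc                   # enrichment per selected PC, with directions
result.candidates                   # biomarker candidates at sensitivity > 0.65
```
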