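"""End-to-end orchestration: simulate/ingest -> QC -> bias correction ->
normalization -> feature selection -> PCA -> per-PC GSEA with direction
inference -> DGE -> biomarker screen -> cell-type enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dge as dge_mod
from . import hvg, normalize, pca, qc, roc
from .celltype import celltype_gsea, derive_markers, markers_to_collection, rank_biomarkers
from .gsea import EnrichmentResult, gsea_preranked, infer_direction, make_ranked
from .io import CountMatrix, GeneSetCollection
from .simulate import LabeledReference

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    qc_flags: pd.Series | None = None
    counts_corrected: CountMatrix | None = None
    bias_model: normalize.BiasModel | None = None
    size_factors: normalize.SizeFactors | None = None
    expression: pd.DataFrame | None = None  # normalized log2, selected genes
    fluctuation: hvg.FluctuationResult | None = None
    pca_result: pca.PCAResult | None = None
    pc_correlation: pca.PCCorrelation | None = None
    gsea_by_pc: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    dge_table: pd.DataFrame | None = None
    screen: pd.DataFrame | None = None
    candidates: pd.DataFrame | None = None
    celltype_by_ranking: dict[str, list[EnrichmentResult]] = field(default_factory=dict)


def run_pipeline(
    counts: CountMatrix,
    meta: pd.DataFrame,
    gene_sets: GeneSetCollection | None = None,
    qc_table: pd.DataFrame | None = None,
    reference: LabeledReference | None = None,
    min_count: int = 5,
    trim_fraction: float = 0.20,
    pc_r_threshold: float = 0.25,
    n_perm: int = 10000,
    n_perm_max: int | None = None,
    fpr: float = 0.10,
    min_sensitivity: float = 0.65,
    n_boot: int = 2000,
    include_metadata_variables: bool = True,
    run_dge: bool = True,
    run_screen: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis; heavy stages can be toggled off."""
    res = PipelineResult()

    if qc_table is not None:
        flags, _ = qc.detect_outliers_iqr(qc_table)
        res.qc_flags = flags
        keep = flags.index[~flags]
        counts = counts.subset_samples(keep)
        meta = meta.loc[keep]
        logger.info("pipeline: %d samples retained after QC", counts.n_samples)

    counts = normalize.filter_low_counts(counts, mode="global", min_count=min_count)
    corrected, bias_model = normalize.correct_library_bias(counts)
    res.counts_corrected, res.bias_model = corrected, bias_model

    factors = normalize.estimate_spikein_size_factors(corrected)
    res.size_factors = factors
    norm_log = normalize.normalize_offset_log(corrected, factors)

    spikes = corrected.is_spikein.to_numpy()
    fit = hvg.fit_technical_noise(
        normalize.normalized_counts(corrected, factors).loc[spikes]
    )
    fluct = hvg.test_fluctuation(
        normalize.normalized_counts(corrected, factors), fit, corrected.is_spikein
    )
    res.fluctuation = fluct
    expr = norm_log.loc[fluct.selected]

    expr = pca.trim_low_variance(expr, remove_fraction=trim_fraction)
    res.expression = expr
    pca_res = pca.run_pca(expr)
    res.pca_result = pca_res
    corr = pca.correlate_pcs(pca_res, meta, threshold=pc_r_threshold)
    res.pc_correlation = corr

    if gene_sets is not None:
        # rank only non-spike-in genes; spike-ins carry no pathway meaning
        bio = expr.index[~corrected.is_spikein.loc[expr.index].to_numpy()]
        for pc_name in corr.selected:
            ranked = make_ranked(pca_res.loadings.loc[bio, pc_name],
                                 source=f"{pc_name} loading")
            results = gsea_preranked(
                ranked, gene_sets, n_perm=n_perm, seed=seed,
                n_perm_max=n_perm_max,
            )
            r_pc = corr.condition_r[pc_name]
            for r in results:
                r.direction = infer_direction(r.nes, r_pc)
            res.gsea_by_pc[pc_name] = results

    if run_dge:
        grouped = normalize.filter_low_counts(
            corrected, mode="group", min_count=min_count,
            min_samples=int(meta["condition"].value_counts().min()),
        )
        res.dge_table = dge_mod.run_dge(grouped, meta, factors)

    if run_screen:
        variables = expr.loc[~corrected.is_spikein.loc[expr.index].to_numpy()]
        if include_metadata_variables:
            extra = pca.encode_covariates(meta.drop(columns=["condition"]))
            variables = pd.concat([variables, extra.T.loc[:, variables.columns]])
        labels = (meta.loc[variables.columns, "condition"] == "PE").to_numpy()
        screen = roc.screen_variables(
            variables, labels, fpr=fpr, n_boot=n_boot, seed=seed
        )
        res.screen = screen
        res.candidates = roc.filter_candidates(screen, min_sensitivity=min_sensitivity)

        if reference is not None:
            markers = derive_markers(ref=reference)
            collection = markers_to_collection(markers)
            for by in ("auc", "sensitivity"):
                ranked = rank_biomarkers(screen, by=by)
                res.celltype_by_ranking[by] = celltype_gsea(
                    ranked, collection, n_perm=n_perm, seed=seed,
                    n_perm_max=n_perm_max,
                )

    return res
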