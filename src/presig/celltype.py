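"""Cell-type marker derivation from a labelled reference and enrichment of
marker signatures in biomarker rankings."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gsea import EnrichmentResult, RankedList, gsea_preranked, make_ranked
from .io import GeneSet, GeneSetCollection
from .simulate import LabeledReference

logger = logging.getLogger(__name__)

#: progenitor-style labels dropped by default before marker derivation
DEFAULT_LABEL_BLACKLIST = (
    "hematopoietic_stem_cells",
    "granulocyte_monocyte_progenitors",
    "B_cell_progenitors",
    "NK_cell_progenitors",
    "multi_lymphoid_progenitors",
    "lymphoid_primed_multipotent_progenitors",
    "megakaryocyte_erythroid_progenitors",
    "common_myeloid_progenitors",
    "multipotent_progenitors",
)


@dataclass
class MarkerSet:
    cell_type: str
    genes: tuple[str, ...]
    log2fc: pd.Series
    padj: pd.Series


def _cp10k(counts: pd.DataFrame) -> np.ndarray:
    """Counts-per-10k column normalisation (log1p applied downstream where
    needed; fold-changes use the linear CP10k scale with pseudocount 1)."""
    x = counts.to_numpy(dtype=float)
    tot = x.sum(axis=0)
    return x / np.maximum(tot, 1.0) * 1e4


def derive_markers(
    ref: LabeledReference,
    lfc_min: float = 2.32,
    alpha: float = 0.05,
    label_blacklist: tuple[str, ...] = DEFAULT_LABEL_BLACKLIST,
) -> list[MarkerSet]:
    """One-vs-rest marker derivation per retained cell type.

    log2FC of mean CP10k expression (pseudocount 1) and a two-sided
    rank-sum p per gene, BH-adjusted within each comparison; markers must
    satisfy log2FC > lfc_min (strict) and padj < alpha.  Blacklisted labels
    are dropped before derivation.
    """
    keep = ~ref.labels.isin(label_blacklist)
    labels = ref.labels[keep]
    counts = ref.counts.loc[:, keep.to_numpy()]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types after blacklist")
    norm = _cp10k(counts)
    lab = labels.to_numpy()

    out: list[MarkerSet] = []
    for t in types:
        m = lab == t
        if m.sum() < 3:
            warnings.warn(f"cell type {t!r} has < 3 cells, skipped", stacklevel=2)
            continue
        a = norm[:, m]
        b = norm[:, ~m]
        log2fc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))
        p = stats.mannwhitneyu(a, b, alternative="two-sided", axis=1).pvalue
        padj = multipletests(p, method="fdr_bh")[1]
        sel = (log2fc > lfc_min) & (padj < alpha)
        genes = tuple(ref.counts.index[sel])
        if genes:
            out.append(
                MarkerSet(
                    cell_type=t,
                    genes=genes,
                    log2fc=pd.Series(log2fc[sel], index=genes),
                    padj=pd.Series(padj[sel], index=genes),
                )
            )
        logger.info("derive_markers: %s -> %d markers", t, int(sel.sum()))
    return out


def markers_to_collection(markers: list[MarkerSet]) -> GeneSetCollection:
    return GeneSetCollection(
        [GeneSet(m.cell_type, "cell-type markers", m.genes) for m in markers]
    )


def rank_biomarkers(results: pd.DataFrame, by: str = "auc") -> RankedList:
    """Descending ranking of screened variables by 'auc' or 'sensitivity'."""
    if by not in ("auc", "sensitivity"):
        raise ValueError("by must be 'auc' or 'sensitivity'")
    return make_ranked(results[by], source=by.upper() if by == "auc" else by)


def celltype_gsea(
    ranked: RankedList,
    markers: list[MarkerSet] | GeneSetCollection,
    n_perm: int = 10000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    n_perm_max: int | None = None,
) -> list[EnrichmentResult]:
    """Marker-set enrichment in a biomarker ranking (same engine as pathway
    GSEA); positive NES maps to a 'Positive' predictive role, negative to
    'Negative'."""
    if not isinstance(markers, GeneSetCollection):
        markers = markers_to_collection(markers)
    results = gsea_preranked(
        ranked, markers, n_perm=n_perm, min_size=min_size, max_size=max_size,
        seed=seed, n_perm_max=n_perm_max,
    )
    for r in results:
        r.direction = predictive_role(r.nes)
    return results


def predictive_role(nes: float) -> str:
    if nes == 0 or np.isnan(nes):
        return "n/a"
    return "Positive" if nes > 0 else "Negative"
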