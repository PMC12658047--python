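"""Per-gene negative-binomial Wald differential-expression test.

Simplified NB GLM with a condition covariate and log size-factor offset;
dispersion by per-gene (Cox-Reid adjusted) maximum likelihood with a
trend-smoothed fallback for low-information genes; BH adjustment.  No
shrinkage of fold-changes or dispersions is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._nbfit import _solve_means, fit_nb_groups
from .io import CountMatrix
from .normalize import SizeFactors

logger = logging.getLogger(__name__)


def _trend_dispersion(base_mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Log-linear trend of dispersion vs mean, fitted on genes with
    interior estimates; used as a fallback for low-information genes whose
    per-gene ML lands implausibly far below the trend."""
    ok = (alpha > 1e-6) & (alpha < 10.0) & (base_mean > 0)
    if ok.sum() < 20:
        return np.full_like(alpha, np.median(alpha[ok]) if ok.any() else 0.1)
    lx = np.log(base_mean[ok])
    ly = np.log(alpha[ok])
    b, a = np.polyfit(lx, ly, 1)
    return np.exp(a + b * np.log(np.maximum(base_mean, 1e-8)))


def run_dge(
    cm: CountMatrix,
    meta: pd.DataFrame,
    factors: SizeFactors,
    alpha: float = 0.05,
    condition_col: str = "condition",
) -> pd.DataFrame:
    """NB Wald test of PE vs NP per gene.

    Returns a table with DESeq2-style columns (baseMean, log2FoldChange,
    stat, pvalue, padj), excluding genes that are all-zero in both groups.
    The Wald statistic is referred to the t distribution with n - 2 degrees
    of freedom (slightly heavier-tailed than the normal, compensating for
    the estimated dispersion at small n).
    """
    cond = meta.loc[cm.sample_ids, condition_col].to_numpy()
    levels = sorted(pd.unique(cond))
    if len(levels) != 2:
        raise ValueError("need exactly two conditions")
    # code so that group 1 == PE when present (log2FC is PE vs NP)
    ref, alt = ("NP", "PE") if set(levels) == {"NP", "PE"} else tuple(levels)
    groups = (cond == alt).astype(np.int64)
    if min((groups == 0).sum(), (groups == 1).sum()) < 3:
        raise ValueError("need >= 3 samples per condition")

    y = cm.counts.to_numpy()
    nonzero = y.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("run_dge: excluding %d all-zero genes", int((~nonzero).sum()))
    yf = y[nonzero].astype(float)
    genes = cm.gene_ids[nonzero]
    f = factors.factors.loc[cm.sample_ids].to_numpy()

    fit = fit_nb_groups(yf, f, groups)
    alpha_fit = fit.alpha.copy()
    base_mean = (yf / f[None, :]).mean(axis=1)
    trend = _trend_dispersion(base_mean, alpha_fit)
    low_info = (alpha_fit < trend / 4.0) | ~fit.converged
    if low_info.any():
        logger.info(
            "run_dge: %d low-information dispersions set to trend", int(low_info.sum())
        )
        alpha_fit[low_info] = trend[low_info]
    c, _ = _solve_means(yf, f, groups, alpha_fit)
    # continuity floor for groups with zero counts so the ratio stays finite
    floor = 0.5 / f.sum()
    c = np.maximum(c, floor)

    log2fc = np.log2(c[:, 1] / c[:, 0])
    mu = c[:, groups] * f[None, :]
    w = mu / (1.0 + alpha_fit[:, None] * mu)
    se = np.sqrt(1.0 / w[:, groups == 0].sum(axis=1) + 1.0 / w[:, groups == 1].sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.log(c[:, 1] / c[:, 0]) / se
    df_t = len(groups) - 2
    p = 2.0 * stats.t.sf(np.abs(stat), df=df_t)
    p = np.where(np.isfinite(stat), p, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "stat": stat,
            "pvalue": p,
            "padj": padj,
        },
        index=genes,
    )
    logger.info(
        "run_dge: %d genes tested, %d at padj < %g",
        len(table), int((table["padj"] < alpha).sum()), alpha,
    )
    return table
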