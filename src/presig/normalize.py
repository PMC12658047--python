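"""Low-count filtering, spike-in-anchored size factors, offset+log transform,
and per-gene negative-binomial library-bias correction."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nbfit import fit_nb_groups
from .io import CountMatrix

logger = logging.getLogger(__name__)
LOG2E = np.log2(np.e)


@dataclass
class SizeFactors:
    """Per-sample positive scale factors, geometric mean 1, anchored on the
    spike-ins listed in ``reference``."""

    factors: pd.Series
    reference: list[str]

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")
        gm = np.exp(np.log(self.factors.to_numpy()).mean())
        if not np.isclose(gm, 1.0, rtol=1e-6):
            raise ValueError(f"size factors not normalised (geometric mean {gm})")


@dataclass
class BiasModel:
    """Per-gene log2 library-bias estimates (library 2 vs library 1)."""

    table: pd.DataFrame  # columns: bias_log2, converged

    @property
    def bias_log2(self) -> pd.Series:
        return self.table["bias_log2"]

    @property
    def converged(self) -> pd.Series:
        return self.table["converged"]


def filter_low_counts(
    cm: CountMatrix,
    mode: str = "global",
    min_count: int = 5,
    min_samples: int | None = None,
) -> CountMatrix:
    """Drop weakly expressed genes; spike-in rows are never dropped.

    mode="global" drops genes whose total count is below ``min_count``;
    mode="group" drops genes having at least ``min_count`` counts in fewer
    than ``min_samples`` samples (pass the smallest group size).
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = cm.counts.to_numpy()
    if mode == "global":
        keep = counts.sum(axis=1) >= min_count
    elif mode == "group":
        if min_samples is None:
            raise ValueError("mode='group' requires min_samples")
        if min_samples > cm.n_samples:
            raise ValueError("min_samples exceeds the number of samples")
        keep = (counts >= min_count).sum(axis=1) >= min_samples
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep |= cm.is_spikein.to_numpy()
    out = cm.subset_genes(cm.gene_ids[keep])
    logger.info(
        "filter_low_counts(%s): %d -> %d genes (%d spike-ins retained)",
        mode, cm.n_genes, out.n_genes, int(out.is_spikein.sum()),
    )
    return out


def estimate_spikein_size_factors(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors restricted to spike-in rows.

    Spike-ins with a zero count in any sample are excluded from the
    reference (and logged); factors are rescaled to geometric mean 1.
    """
    cm.require_spikeins()
    spikes = cm.counts.loc[cm.is_spikein.to_numpy()]
    nonzero = (spikes.to_numpy() > 0).all(axis=1)
    excluded = spikes.index[~nonzero]
    if len(excluded):
        logger.info(
            "estimate_spikein_size_factors: excluding %d spike-ins with zeros: %s%s",
            len(excluded), list(excluded[:5]), "..." if len(excluded) > 5 else "",
        )
    ref = spikes.loc[nonzero]
    if ref.shape[0] < 2:
        raise ValueError(
            "fewer than 2 spike-ins are non-zero in every sample; "
            "use a pseudo-reference fallback (--pseudo-reference) instead"
        )
    logref = np.log(ref.to_numpy())
    geomean = logref.mean(axis=1)
    ratios = logref - geomean[:, None]
    logf = np.median(ratios, axis=0)
    logf -= logf.mean()  # geometric mean 1
    factors = pd.Series(np.exp(logf), index=cm.sample_ids, name="size_factor")
    return SizeFactors(factors, list(ref.index))


def normalize_offset_log(
    cm_or_counts, factors: SizeFactors, offset: float = 1.0
) -> pd.DataFrame:
    """value(g, s) = log2(count(g, s) / factor_s + offset)."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    counts = cm_or_counts.counts if isinstance(cm_or_counts, CountMatrix) else cm_or_counts
    f = factors.factors.loc[counts.columns].to_numpy()
    return pd.DataFrame(
        np.log2(counts.to_numpy() / f[None, :] + offset),
        index=counts.index,
        columns=counts.columns,
    )


def normalized_counts(cm: CountMatrix, factors: SizeFactors) -> pd.DataFrame:
    """Plain count / size-factor matrix (no log)."""
    f = factors.factors.loc[cm.sample_ids].to_numpy()
    return cm.counts / f[None, :]


def correct_library_bias(
    cm: CountMatrix, factors: SizeFactors | None = None
) -> tuple[CountMatrix, BiasModel]:
    """Estimate and divide out a per-gene multiplicative library effect.

    Per gene an NB log-linear model with the log size factor as offset and
    the library indicator as covariate is fitted; corrected counts are
    ``round(count / 2**(bias_g * [s in library 2]))`` (round-half-to-even,
    floored at 0) so the matrix stays a valid count matrix.  Genes failing
    convergence pass through uncorrected with a flag.
    """
    if cm.library is None:
        raise ValueError("count matrix has no library labels")
    libs = sorted(pd.unique(cm.library))
    if len(libs) == 1:
        warnings.warn("single library: bias correction is the identity", stacklevel=2)
        table = pd.DataFrame(
            {"bias_log2": 0.0, "converged": False}, index=cm.gene_ids
        )
        return cm, BiasModel(table)
    if len(libs) != 2:
        raise ValueError(f"expected exactly 2 library labels, got {libs}")
    groups = (cm.library.to_numpy() == libs[1]).astype(np.int64)
    if min((groups == 0).sum(), (groups == 1).sum()) < 3:
        raise ValueError("need >= 3 samples per library")

    if factors is None:
        if int(cm.is_spikein.sum()) >= 2:
            factors = estimate_spikein_size_factors(cm)
        else:  # fall back to library-size factors
            tot = cm.counts.sum(axis=0).astype(float)
            f = tot / np.exp(np.log(tot).mean())
            factors = SizeFactors(pd.Series(f, index=cm.sample_ids), [])

    y = cm.counts.to_numpy()
    fit = fit_nb_groups(y, factors.factors.to_numpy(), groups)
    c = fit.group_means
    estimable = fit.converged & (c[:, 0] > 0) & (c[:, 1] > 0)
    bias = np.zeros(cm.n_genes)
    bias[estimable] = np.log2(c[estimable, 1] / c[estimable, 0])

    corr = y.astype(float).copy()
    lib2 = groups == 1
    corr[np.ix_(estimable, lib2)] /= np.exp2(bias[estimable])[:, None]
    corr = np.maximum(_round_half_even(corr), 0).astype(np.int64)

    table = pd.DataFrame(
        {"bias_log2": bias, "converged": estimable}, index=cm.gene_ids
    )
    logger.info(
        "correct_library_bias: %d/%d genes corrected (median |bias| %.3f log2)",
        int(estimable.sum()), cm.n_genes,
        float(np.median(np.abs(bias[estimable]))) if estimable.any() else float("nan"),
    )
    out = CountMatrix(
        pd.DataFrame(corr, index=cm.gene_ids, columns=cm.sample_ids),
        cm.is_spikein,
        cm.library,
    )
    return out, BiasModel(table)


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x)
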