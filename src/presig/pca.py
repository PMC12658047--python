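"""PCA of the normalized expression matrix, variance-based trimming, and
PC-covariate correlation screening."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def trim_low_variance(expr: pd.DataFrame, remove_fraction: float = 0.20) -> pd.DataFrame:
    """Drop the ``remove_fraction`` of variables (rows) with the lowest
    variance across samples; ties broken by variable id (lexicographically
    smaller id drops first)."""
    if not (0 <= remove_fraction < 1):
        raise ValueError("remove_fraction must be in [0, 1)")
    var = expr.var(axis=1, ddof=1)
    if (var == 0).all():
        raise ValueError("all variables are constant")
    if remove_fraction == 0:
        return expr
    order = sorted(expr.index, key=lambda g: (var[g], g))
    n_drop = int(np.floor(remove_fraction * expr.shape[0] + 1e-9))
    keep = [g for g in expr.index if g not in set(order[:n_drop])]
    logger.info("trim_low_variance: %d -> %d variables", expr.shape[0], len(keep))
    return expr.loc[keep]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # genes x PCs (unit-norm columns)
    pct_variance: pd.Series  # per retained PC, denominator = total variance
    n_pcs: int
    eigenvalues: np.ndarray = field(repr=False, default=None)


def run_pca(expr: pd.DataFrame, max_pcs: int = 30) -> PCAResult:
    """SVD-based PCA of samples in variable space.

    Variables (rows of ``expr``) are centred and unit-variance scaled; the
    percentage of variance uses the full trace so values over all PCs sum to
    100.  Sign convention: the largest-|entry| element of each loading
    vector is positive.
    """
    if expr.shape[1] < 2 or expr.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 variables")
    X = expr.to_numpy(dtype=float).T  # samples x variables
    if not np.isfinite(X).all():
        raise ValueError("missing values in expression matrix")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = expr.index[np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-variance variables reached PCA: {list(bad)}")
    Xs = (X - X.mean(axis=0)) / sd

    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    n = X.shape[0]
    lam = S**2 / (n - 1)
    total = lam.sum()
    n_keep = min(n - 1, max_pcs, len(S))

    scores = U[:, :n_keep] * S[:n_keep]
    loadings = Vt[:n_keep].T
    # sign convention
    for k in range(n_keep):
        i = np.argmax(np.abs(loadings[:, k]))
        if loadings[i, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    pcs = [f"PC{k + 1}" for k in range(n_keep)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=pcs),
        loadings=pd.DataFrame(loadings, index=expr.index, columns=pcs),
        pct_variance=pd.Series(100.0 * lam[:n_keep] / total, index=pcs),
        n_pcs=n_keep,
        eigenvalues=lam,
    )


#: default numeric encoding for binary covariates, recorded in output
BINARY_ENCODING = {
    "condition": {"PE": 1, "NP": 0},
    "child_sex": {"male": 1, "female": 0},
    "library": {2: 1, 1: 0},
}


def encode_covariates(meta: pd.DataFrame) -> pd.DataFrame:
    """Numeric / binary encoding of metadata columns (PE=1, male=1, lib2=1)."""
    out = {}
    for col in meta.columns:
        s = meta[col]
        if col in BINARY_ENCODING:
            out[col] = s.map(BINARY_ENCODING[col]).astype(float)
        elif pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        # non-numeric columns without a known encoding are skipped
    return pd.DataFrame(out, index=meta.index)


@dataclass
class PCCorrelation:
    matrix: pd.DataFrame  # PCs x covariates, Pearson r
    selected: list[str]  # PCs with |r| >= threshold vs condition
    condition_r: pd.Series  # r of each PC against condition
    threshold: float


def correlate_pcs(
    pca: PCAResult,
    meta: pd.DataFrame,
    threshold: float = 0.25,
    condition_col: str = "condition",
) -> PCCorrelation:
    """Pearson (point-biserial for binaries) correlation of each PC score
    vector against each covariate; PCs with |r| >= threshold against the
    condition are selected (inclusive rule)."""
    cov = encode_covariates(meta.loc[pca.scores.index])
    rmat = pd.DataFrame(index=pca.scores.columns, columns=cov.columns, dtype=float)
    for c in cov.columns:
        x = cov[c].to_numpy()
        if np.nanstd(x) == 0 or np.isnan(x).all():
            rmat[c] = np.nan  # constant covariate: correlation undefined
            continue
        ok = ~np.isnan(x)
        xs = x[ok] - x[ok].mean()
        S = pca.scores.to_numpy()[ok]
        Sc = S - S.mean(axis=0)
        denom = np.sqrt((Sc**2).sum(axis=0) * (xs**2).sum())
        rmat[c] = (Sc.T @ xs) / denom
    cond_r = rmat[condition_col]
    # inclusive rule; tiny slack so r computed exactly at the threshold is kept
    selected = [pc for pc in rmat.index if abs(cond_r[pc]) >= threshold - 1e-12]
    logger.info(
        "correlate_pcs: selected %s at |r|>=%g vs %s", selected, threshold, condition_col
    )
    return PCCorrelation(rmat, selected, cond_r, threshold)
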