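"""Per-variable ROC screening of a binary condition.

Single-predictor logistic models orient each variable; AUC with DeLong CI
and a one-sided Mann-Whitney p (AUC > 0.5); sensitivity / specificity /
accuracy at a fixed false-positive rate with stratified-bootstrap percentile
CIs.  Evaluation is in-sample (apparent performance) by design; callers are
reminded of this in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# AUC / Mann-Whitney
# ---------------------------------------------------------------------------

def auc_mannwhitney(scores, labels) -> tuple[float, float]:
    """AUC = U / (n1 n2) with ties counted 1/2, and the one-sided
    (AUC > 0.5) normal-approximation p with tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)

    n = n1 + n0
    _, counts = np.unique(scores, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(auc), 0.5  # all scores identical
    z = (u - n1 * n0 / 2.0 - 0.5) / np.sqrt(var_u)  # continuity corrected
    return float(auc), float(stats.norm.sf(z))


def delong_auc_variance(scores, labels) -> float:
    """DeLong variance of the empirical AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    n1, n0 = len(pos), len(neg)
    # placements via midranks
    all_r = stats.rankdata(scores)
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[labels] - pos_r) / n0  # P(neg < pos_i) per positive
    v01 = 1.0 - (all_r[~labels] - neg_r) / n1  # P(pos > neg_j) per negative
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """(AUC, lo, hi) by the DeLong normal interval, clipped to [0, 1]."""
    auc, _ = auc_mannwhitney(scores, labels)
    se = np.sqrt(delong_auc_variance(scores, labels))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return auc, float(np.clip(auc - zq * se, 0, 1)), float(np.clip(auc + zq * se, 0, 1))


# ---------------------------------------------------------------------------
# operating point at fixed FPR
# ---------------------------------------------------------------------------

def _threshold_at_fpr(neg: np.ndarray, fpr: float) -> float:
    """Most permissive cutoff t (predict positive when score > t) whose
    empirical FPR is <= fpr: the (k+1)-th largest negative score where
    k = floor(fpr * n0)."""
    k = int(np.floor(fpr * len(neg) + 1e-9))
    k = min(k, len(neg) - 1)
    return float(np.partition(neg, len(neg) - 1 - k)[len(neg) - 1 - k])


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]


def operating_point(
    scores,
    labels,
    fpr: float = 0.10,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> OperatingPoint:
    """Sensitivity / specificity / accuracy at the fixed-FPR threshold with
    stratified-bootstrap percentile CIs (resampling within class)."""
    if not (0 < fpr < 1):
        raise ValueError("fpr must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")

    t = _threshold_at_fpr(neg, fpr)
    sens = float(np.mean(pos > t))
    spec = float(np.mean(neg <= t))
    acc = float((np.sum(pos > t) + np.sum(neg <= t)) / len(scores))
    if sens == 0.0:
        logger.info("operating_point: no positive calls at FPR <= %g", fpr)

    rng = np.random.default_rng(seed)
    bs, bp, ba = _bootstrap_operating(pos, neg, fpr, n_boot, rng)
    qlo, qhi = (1 - level) / 2.0, 1 - (1 - level) / 2.0
    return OperatingPoint(
        threshold=t,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=(float(np.quantile(bs, qlo)), float(np.quantile(bs, qhi))),
        specificity_ci=(float(np.quantile(bp, qlo)), float(np.quantile(bp, qhi))),
        accuracy_ci=(float(np.quantile(ba, qlo)), float(np.quantile(ba, qhi))),
    )


def _bootstrap_operating(pos, neg, fpr, n_boot, rng, idx_pos=None, idx_neg=None):
    n1, n0 = len(pos), len(neg)
    if idx_pos is None:
        idx_pos = rng.integers(0, n1, size=(n_boot, n1))
    if idx_neg is None:
        idx_neg = rng.integers(0, n0, size=(n_boot, n0))
    pb = pos[idx_pos]
    nb = neg[idx_neg]
    k = int(np.floor(fpr * n0 + 1e-9))
    k = min(k, n0 - 1)
    t = np.partition(nb, n0 - 1 - k, axis=1)[:, n0 - 1 - k]
    sens = (pb > t[:, None]).mean(axis=1)
    spec = (nb <= t[:, None]).mean(axis=1)
    acc = (sens * n1 + spec * n0) / (n1 + n0)
    return sens, spec, acc


# ---------------------------------------------------------------------------
# logistic orientation (vectorised across variables)
# ---------------------------------------------------------------------------

def _fit_logistic_batch(X: np.ndarray, y: np.ndarray, n_iter: int = 30):
    """Newton fits of one single-predictor logistic model per row of X.

    Predictors are standardised internally; returns the standardised slope
    and a separation/convergence flag per variable.
    """
    G, n = X.shape
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    b0 = np.zeros(G)
    b1 = np.zeros(G)
    yb = y.astype(float)
    flagged = np.zeros(G, dtype=bool)
    for _ in range(n_iter):
        eta = b0[:, None] + b1[:, None] * Z
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1 - p)
        r = yb[None, :] - p
        g0 = r.sum(axis=1)
        g1 = (r * Z).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * Z).sum(axis=1)
        h11 = (w * Z * Z).sum(axis=1)
        det = h00 * h11 - h01**2
        bad = det < 1e-12
        det[bad] = 1.0
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0[bad] = 0.0
        d1[bad] = 0.0
        step = np.sqrt(d0**2 + d1**2)
        big = step > 5.0  # dampen near-separation blow-ups
        d0[big] *= 5.0 / step[big]
        d1[big] *= 5.0 / step[big]
        b0 += d0
        b1 += d1
        flagged |= bad
    flagged |= np.abs(b1) > 15.0  # quasi-complete separation
    return b1, flagged


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def screen_variables(
    variables: pd.DataFrame,
    labels,
    fpr: float = 0.10,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """One ROC row per variable (variables x samples orientation).

    A single-predictor logistic model orients each variable (for a monotone
    predictor the fitted-probability ROC equals the raw variable's up to
    orientation, which is exploited); separated models fall back to the raw
    variable with a flag.  AUCs are apparent (in-sample) estimates.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    X = variables.to_numpy(dtype=float)
    G, n = X.shape
    logger.info(
        "screen_variables: %d variables, %d samples; NOTE apparent "
        "(in-sample) performance, expect wide CIs", G, n,
    )
    n1 = int(labels.sum())
    n0 = n - n1

    slope, flagged = _fit_logistic_batch(X, labels)
    orient = np.where(slope >= 0, 1.0, -1.0)
    S = X * orient[:, None]  # oriented scores, ROC-equivalent to fitted probs

    # vectorised AUC + MW p
    ranks = stats.rankdata(S, axis=1)
    u = ranks[:, labels].sum(axis=1) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    var_u = np.empty(G)
    for i in range(G):  # tie-corrected variance needs per-variable tie counts
        _, cnt = np.unique(S[i], return_counts=True)
        tie = np.sum(cnt**3 - cnt) / (n * (n - 1))
        var_u[i] = n1 * n0 / 12.0 * ((n + 1) - tie)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - n1 * n0 / 2.0 - 0.5) / np.sqrt(var_u)
    auc_p = np.where(var_u > 0, stats.norm.sf(z), 0.5)

    # DeLong CI, vectorised
    pos_r = stats.rankdata(S[:, labels], axis=1)
    neg_r = stats.rankdata(S[:, ~labels], axis=1)
    v10 = (ranks[:, labels] - pos_r) / n0
    v01 = 1.0 - (ranks[:, ~labels] - neg_r) / n1
    se = np.sqrt(v10.var(axis=1, ddof=1) / n1 + v01.var(axis=1, ddof=1) / n0)
    zq = stats.norm.ppf(0.975)
    auc_lo = np.clip(auc - zq * se, 0, 1)
    auc_hi = np.clip(auc + zq * se, 0, 1)

    # operating point + bootstrap CIs with shared resampling indices
    rng = np.random.default_rng(seed)
    idx_pos = rng.integers(0, n1, size=(n_boot, n1))
    idx_neg = rng.integers(0, n0, size=(n_boot, n0))
    k = int(np.floor(fpr * n0 + 1e-9))
    k = min(k, n0 - 1)
    sens = np.empty(G)
    spec = np.empty(G)
    acc = np.empty(G)
    thr = np.empty(G)
    sens_ci = np.empty((G, 2))
    wilcox_p = np.empty(G)
    for i in range(G):
        pos = S[i, labels]
        neg = S[i, ~labels]
        t = float(np.partition(neg, n0 - 1 - k)[n0 - 1 - k])
        thr[i] = t
        sens[i] = np.mean(pos > t)
        spec[i] = np.mean(neg <= t)
        acc[i] = (sens[i] * n1 + spec[i] * n0) / n
        bs, _, _ = _bootstrap_operating(
            pos, neg, fpr, n_boot, rng, idx_pos=idx_pos, idx_neg=idx_neg
        )
        sens_ci[i] = np.quantile(bs, [0.025, 0.975])
        wilcox_p[i] = wilcoxon_group_test(X[i], labels)

    out = pd.DataFrame(
        {
            "auc": auc,
            "auc_lo": auc_lo,
            "auc_hi": auc_hi,
            "auc_p": auc_p,
            "sensitivity": sens,
            "sens_lo": sens_ci[:, 0],
            "sens_hi": sens_ci[:, 1],
            "specificity": spec,
            "accuracy": acc,
            "threshold": thr,
            "orientation": orient,
            "wilcoxon_p": wilcox_p,
            "logistic_flagged": flagged,
        },
        index=variables.index,
    )
    return out


def filter_candidates(results: pd.DataFrame, min_sensitivity: float = 0.65) -> pd.DataFrame:
    """Strictly-greater sensitivity filter, sorted by AUC descending."""
    kept = results[results["sensitivity"] > min_sensitivity]
    return kept.sort_values("auc", ascending=False, kind="stable")


def wilcoxon_group_test(values, labels) -> float:
    """Two-sided rank-sum p; exact when sample sizes are modest and there
    are no ties, asymptotic with tie correction otherwise."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    x = values[labels]
    y = values[~labels]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(values == values[0]):
        return 1.0
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (no_ties and max(len(x), len(y)) <= 60) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
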