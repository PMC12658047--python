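"""Fluctuation-based feature selection.

Each gene's squared coefficient of variation (CV^2) of normalised counts is
compared with the technical CV^2 predicted at its mean from a curve fitted
to the spike-ins, CV2_tech(mu) = a1/mu + alpha0.  The per-gene statistic
(n-1) * CV2_obs / CV2_tech(mu) is referred to the chi-square distribution
with n-1 degrees of freedom (upper tail) and BH-adjusted across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class NoiseFit:
    a1: float  # coefficient of the 1/mu term
    alpha0: float  # asymptotic CV^2 floor
    n_spikeins: int
    residual_deviance: float

    def predict(self, mean: np.ndarray) -> np.ndarray:
        """Technical CV^2 at the given means."""
        mean = np.asarray(mean, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a1 / mean + self.alpha0


def _mean_cv2(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = mat.mean(axis=1)
    v = mat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(m > 0, v / m**2, np.nan)
    return m, cv2


def fit_technical_noise(norm_spikes: pd.DataFrame) -> NoiseFit:
    """Fit CV2_tech(mu) = a1/mu + alpha0 to spike-in (mean, CV^2) pairs by
    gamma-family regression on 1/mu; a1 is clamped at 0 if it fits negative."""
    if norm_spikes.shape[1] < 2:
        raise ValueError("CV^2 undefined with a single sample")
    m, cv2 = _mean_cv2(norm_spikes.to_numpy(dtype=float))
    keep = (m > 0) & np.isfinite(cv2) & (cv2 > 0)
    m, cv2 = m[keep], cv2[keep]
    if len(m) < 10:
        raise ValueError(f"need >= 10 spike-ins with positive mean, got {len(m)}")
    if np.allclose(m, m[0]):
        raise ValueError("degenerate spike-in spread: all means equal")

    X = sm.add_constant(1.0 / m)
    start = np.maximum(np.linalg.lstsq(X, cv2, rcond=None)[0], 1e-12)
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # identity-link domain warning
            model = sm.GLM(cv2, X, family=sm.families.Gamma(sm.families.links.Identity()))
            res = model.fit(start_params=start)
        alpha0, a1 = res.params
        dev = float(res.deviance)
    except Exception:  # fall back to least squares on the same design
        alpha0, a1 = np.linalg.lstsq(X, cv2, rcond=None)[0]
        dev = float(np.sum((cv2 - X @ np.array([alpha0, a1])) ** 2))
    if a1 < 0:  # refit without the 1/mu term
        a1 = 0.0
        alpha0 = float(np.mean(cv2))
    elif alpha0 < 0:  # refit through the origin: cv2 ~ a1/mu only
        x = 1.0 / m
        a1 = float(np.sum(x * cv2) / np.sum(x * x))
        alpha0 = 0.0
    alpha0 = max(float(alpha0), 0.0)
    logger.info(
        "fit_technical_noise: a1=%.4g alpha0=%.4g on %d spike-ins", a1, alpha0, len(m)
    )
    return NoiseFit(a1=float(a1), alpha0=alpha0, n_spikeins=len(m), residual_deviance=dev)


@dataclass
class FluctuationResult:
    table: pd.DataFrame  # gene, mean, cv2, cv2_tech, p, padj, fluctuating
    selected: pd.Index  # fluctuating genes plus all spike-ins

    @property
    def fluctuating(self) -> pd.Index:
        return self.table.index[self.table["fluctuating"]]


def test_fluctuation(
    norm_counts: pd.DataFrame,
    fit: NoiseFit,
    is_spikein: pd.Series,
    alpha: float = 0.05,
) -> FluctuationResult:
    """One-sided chi-square test of observed CV^2 exceeding the technical
    prediction; BH across genes.  The selected index keeps fluctuating genes
    plus every spike-in regardless of its p."""
    n = norm_counts.shape[1]
    m, cv2 = _mean_cv2(norm_counts.to_numpy(dtype=float))
    cv2_tech = fit.predict(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (n - 1) * cv2 / cv2_tech
    p = np.where(
        (m > 0) & np.isfinite(stat), stats.chi2.sf(stat, df=n - 1), 1.0
    )
    padj = multipletests(p, method="fdr_bh")[1]
    flags = padj < alpha
    table = pd.DataFrame(
        {
            "mean": m,
            "cv2": cv2,
            "cv2_tech": cv2_tech,
            "p": p,
            "padj": padj,
            "fluctuating": flags,
            "zero_mean": m <= 0,
        },
        index=norm_counts.index,
    )
    spike = is_spikein.reindex(norm_counts.index, fill_value=False).to_numpy()
    selected = norm_counts.index[flags | spike]
    logger.info(
        "test_fluctuation: %d/%d genes fluctuating at padj<%g (+%d spike-ins kept)",
        int((flags & ~spike).sum()), int((~spike).sum()), alpha, int(spike.sum()),
    )
    return FluctuationResult(table=table, selected=selected)
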