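"""Per-sample QC outlier exclusion and cohort comparison statistics."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: the six QC metrics assessed for outliers
QC_METRICS = (
    "mapped_reads",
    "spikein_reads",
    "spikein_5prime_rate",
    "mapped_rate",
    "mapped_spikein_ratio",
    "coding_5prime_rate",
)


def detect_outliers_iqr(qc: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Flag samples with any metric outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (type 7).  Returns the per-sample
    flags and the per-metric fence table.
    """
    if qc.shape[0] < 4:
        raise ValueError("need at least 4 samples for stable quartiles")
    vals = qc.to_numpy(dtype=float)
    q1 = np.quantile(vals, 0.25, axis=0)
    q3 = np.quantile(vals, 0.75, axis=0)
    iqr = q3 - q1
    lo = q1 - 1.5 * iqr
    hi = q3 + 1.5 * iqr
    fences = pd.DataFrame(
        {"q1": q1, "q3": q3, "lower": lo, "upper": hi}, index=qc.columns
    )
    outside = (vals < lo[None, :]) | (vals > hi[None, :])
    flags = pd.Series(outside.any(axis=1), index=qc.index, name="outlier")
    logger.info(
        "detect_outliers_iqr: %d/%d samples flagged", int(flags.sum()), len(flags)
    )
    return flags, fences


def _is_categorical(s: pd.Series) -> bool:
    if not pd.api.types.is_numeric_dtype(s):
        return True
    return s.nunique() <= 3  # parity-style small integer codes


def cohort_summary(
    meta: pd.DataFrame,
    condition_col: str = "condition",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparison table: Shapiro-Wilk-gated Welch t-test vs
    Mann-Whitney U for continuous variables, chi-square (Yates on 2x2) for
    categorical ones.  Reports mean (SD) or counts (%) per group.
    """
    cond = meta[condition_col]
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError("condition must be binary")
    g1 = meta[cond == levels[0]]
    g2 = meta[cond == levels[1]]

    cols = [c for c in meta.columns if c != condition_col]
    if continuous is None and categorical is None:
        continuous = [c for c in cols if not _is_categorical(meta[c])]
        categorical = [c for c in cols if _is_categorical(meta[c])]
    continuous = continuous or []
    categorical = categorical or []

    rows = []
    for col in continuous:
        x1 = g1[col].dropna().to_numpy(dtype=float)
        x2 = g2[col].dropna().to_numpy(dtype=float)
        if min(len(x1), len(x2)) < 3:
            rows.append((col, "", "", "skipped", np.nan, "too few samples"))
            continue
        summ1 = f"{x1.mean():.4g} (±{x1.std(ddof=1):.3g})"
        summ2 = f"{x2.mean():.4g} (±{x2.std(ddof=1):.3g})"
        if x1.std(ddof=1) == 0 or x2.std(ddof=1) == 0:
            rows.append((col, summ1, summ2, "skipped", np.nan, "zero variance"))
            continue
        norm1 = stats.shapiro(x1).pvalue
        norm2 = stats.shapiro(x2).pvalue
        if norm1 > shapiro_alpha and norm2 > shapiro_alpha:
            p = stats.ttest_ind(x1, x2, equal_var=False).pvalue
            test = "welch_t"
        else:
            p = stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue
            test = "mannwhitney_u"
        rows.append((col, summ1, summ2, test, float(p), ""))

    for col in categorical:
        tab = pd.crosstab(meta[col], cond)
        if tab.shape[0] < 2:
            rows.append((col, "", "", "skipped", np.nan, "single level"))
            continue
        c1 = tab[levels[0]]
        c2 = tab[levels[1]]
        summ1 = "; ".join(f"{i}: {v} ({v / c1.sum():.0%})" for i, v in c1.items())
        summ2 = "; ".join(f"{i}: {v} ({v / c2.sum():.0%})" for i, v in c2.items())
        p = chi_square_p(tab.to_numpy())
        rows.append((col, summ1, summ2, "chi_square", float(p), ""))

    return pd.DataFrame(
        rows,
        columns=["variable", levels[0], levels[1], "test", "p", "note"],
    ).set_index("variable")


def chi_square_p(table: np.ndarray) -> float:
    """Chi-square p for a contingency table; Yates correction on 2x2."""
    table = np.asarray(table)
    correction = table.shape == (2, 2)
    return float(stats.chi2_contingency(table, correction=correction).pvalue)
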