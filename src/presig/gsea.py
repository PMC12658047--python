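"""Preranked gene-set enrichment on arbitrary rankings.

Classical weighted Kolmogorov-Smirnov running sum: hit genes increment by
|metric|^p / sum_hits |metric|^p, misses decrement by 1/(N - |S|); the ES is
the signed extremum of the running sum.  The null is gene-sampling: random
sets of equal size drawn from the ranked universe; NES divides the ES by the
mean |null ES| of matching sign, and the two-sided permutation p compares
|ES| against the |null| distribution with add-one smoothing.

Direction-of-change rule: a set is called up in the case group iff
sign(NES) x sign(PC-condition correlation) > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Descending (gene id, metric) ranking with a source tag."""

    metric: pd.Series  # sorted descending, unique index
    source: str = "PC loading"

    def __post_init__(self):
        if self.metric.index.has_duplicates:
            raise ValueError("ranked list has duplicate ids")
        v = self.metric.to_numpy()
        if np.any(v[:-1] < v[1:]):
            raise ValueError("ranked list is not sorted descending")

    def __len__(self) -> int:
        return len(self.metric)


def make_ranked(values: pd.Series, source: str = "PC loading") -> RankedList:
    """Sort descending by metric, ties broken by gene id (ascending)."""
    df = pd.DataFrame({"v": values})
    df = df.sort_index().sort_values("v", ascending=False, kind="stable")
    return RankedList(df["v"], source)


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    leading_edge: tuple[str, ...]
    peak: int  # 0-based index of the extremum in the ranked list


def enrichment_score(ranked: RankedList, gene_set, weight: float = 1.0) -> ESResult:
    """Running-sum enrichment score with leading edge.

    Leading edge: hit genes at or before the extremum for positive ES, and
    strictly after it for negative ES.  Arithmetic is carried out in the
    metric's own numeric type, so exact (rational) inputs stay exact.
    """
    genes = ranked.metric.index
    members = set(gene_set)
    hit = np.array([g in members for g in genes])
    nh = int(hit.sum())
    n = len(genes)
    if nh == 0:
        raise ValueError("gene set has empty intersection with the ranked list")

    if weight == 1:  # avoid ** so exact (rational) metrics stay exact
        w = [abs(m) for m in ranked.metric.to_numpy()]
    else:
        w = [abs(m) ** weight for m in ranked.metric.to_numpy()]
    w_sum = sum(wi for wi, h in zip(w, hit) if h)
    if w_sum == 0:  # all hit metrics zero: fall back to unweighted hits
        w = [1] * n
        w_sum = nh
    one = w_sum / w_sum  # unity in the metric's arithmetic
    miss_dec = 0 if n == nh else one / (n - nh)

    running = np.empty(n, dtype=object)
    s = w_sum - w_sum  # zero in the metric's arithmetic
    for i in range(n):
        if hit[i]:
            s = s + w[i] / w_sum
        else:
            s = s - miss_dec
        running[i] = s

    peak = 0
    for i in range(1, n):
        if abs(running[i]) > abs(running[peak]):
            peak = i
    es = running[peak]
    if es >= 0:
        leading = tuple(genes[i] for i in range(peak + 1) if hit[i])
    else:
        leading = tuple(genes[i] for i in range(peak + 1, n) if hit[i])
    if isinstance(es, (float, np.floating)):
        es = float(es)  # exact (rational) metrics keep their native type
    return ESResult(es=es, running_sum=running, leading_edge=leading, peak=peak)


def _null_es(w: np.ndarray, k: int, n_perm: int, rng: np.random.Generator,
             batch: int = 2000) -> np.ndarray:
    """Null ES for random k-subsets of a ranked universe with hit weights
    ``w`` (already |metric|^p, in ranked order).  Vectorised over batches."""
    n = len(w)
    inv_miss = 1.0 / (n - k) if n > k else 0.0
    out = np.empty(n_perm)
    done = 0
    idx1 = np.arange(1, k + 1, dtype=float)
    while done < n_perm:
        b = min(batch, n_perm - done)
        r = rng.random((b, n), dtype=np.float32)
        pos = np.sort(np.argpartition(r, k - 1, axis=1)[:, :k], axis=1)
        wk = w[pos]
        cw = np.cumsum(wk, axis=1)
        W = cw[:, -1].copy()
        zero = W <= 0
        if zero.any():  # all-zero hit weights: unweighted fallback
            cw[zero] = idx1[None, :]
            wk[zero] = 1.0
            W[zero] = k
        # running sum right after hit i and right before hit i
        after = cw / W[:, None] - (pos + 1 - idx1[None, :]) * inv_miss
        before = after - wk / W[:, None]
        smax = np.maximum(after.max(axis=1), 0.0)
        smin = np.minimum(before.min(axis=1), 0.0)
        out[done : done + b] = np.where(smax >= -smin, smax, smin)
        done += b
    return out


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    padj: float
    size: int
    leading_edge: tuple[str, ...]
    direction: str = "n/a"  # filled by callers that know the PC orientation
    n_perm_used: int = 0


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 10000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    weight: float = 1.0,
    n_perm_max: int | None = None,
) -> list[EnrichmentResult]:
    """Preranked GSEA over a collection with a gene-sampling null.

    When a set's p hits the smoothing floor 1/(n_perm+1), the permutation
    count escalates (doubling, shared per set size) up to ``n_perm_max``
    (default: no escalation).  Sets outside [min_size, max_size] after
    intersection with the universe are excluded and logged.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_perm_max = n_perm if n_perm_max is None else max(n_perm, n_perm_max)
    universe = ranked.metric.index
    n = len(universe)
    if min_size > n:
        raise ValueError("ranked universe smaller than min_size")
    w = np.abs(ranked.metric.to_numpy(dtype=float)) ** weight

    # observed ES per eligible set
    kept: list[tuple[str, ESResult, int]] = []
    uni = set(universe)
    for s in sets:
        inter = [g for g in s.members if g in uni]
        if not inter:
            logger.info("gsea: set %s skipped (empty intersection)", s.name)
            continue
        if not (min_size <= len(inter) <= max_size):
            logger.info(
                "gsea: set %s excluded (size %d outside [%d, %d])",
                s.name, len(inter), min_size, max_size,
            )
            continue
        kept.append((s.name, enrichment_score(ranked, inter, weight), len(inter)))
    if not kept:
        return []

    # nulls are shared across sets of equal size (the null depends only on k)
    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    results = []
    for name, esr, k in kept:
        if k not in nulls:
            nulls[k] = _null_es(w, k, n_perm, rng)
        null = nulls[k]
        while True:
            n_cur = len(null)
            exceed = int(np.sum(np.abs(null) >= abs(esr.es)))
            p = (1 + exceed) / (n_cur + 1)
            if exceed > 0 or n_cur >= n_perm_max:
                break
            null = np.concatenate([null, _null_es(w, k, n_cur, rng)])
            nulls[k] = null
        same = null[np.sign(null) == np.sign(esr.es)] if esr.es != 0 else null
        denom = np.mean(np.abs(same)) if len(same) else np.mean(np.abs(null))
        nes = esr.es / denom if denom > 0 else 0.0
        results.append(
            EnrichmentResult(
                name=name, es=esr.es, nes=float(nes), p=float(p), padj=np.nan,
                size=k, leading_edge=esr.leading_edge, n_perm_used=len(null),
            )
        )

    padj = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, padj):
        r.padj = float(q)
    return results


def infer_direction(nes: float, pc_condition_r: float) -> str:
    """Upregulated iff sign(NES) x sign(r) > 0, else Downregulated."""
    if nes == 0 or pc_condition_r == 0 or np.isnan(nes) or np.isnan(pc_condition_r):
        logger.warning("infer_direction: zero/NaN input, returning n/a")
        return "n/a"
    return "Upregulated" if np.sign(nes) * np.sign(pc_condition_r) > 0 else "Downregulated"


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.name for r in results],
            "size": [r.size for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p": [r.p for r in results],
            "padj": [r.padj for r in results],
            "direction": [r.direction for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    ).set_index("pathway")


def zscore_matrix(
    expr: pd.DataFrame,
    genes,
    pca,
    pc: str,
    leading_edge=(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene Z-scores with rows ordered by loading on ``pc`` (descending)
    and columns by sample score on ``pc``; constant genes become zero rows
    (flagged).  Returns (matrix, leading-edge flags per row)."""
    genes = [g for g in genes if g in expr.index]
    if not genes:
        raise ValueError("no requested genes present in the expression matrix")
    sub = expr.loc[genes]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    flagged = sd == 0
    z = (sub.sub(mu, axis=0)).div(sd.where(sd > 0, 1.0), axis=0)
    z.loc[flagged] = 0.0

    row_order = pca.loadings.loc[genes, pc].sort_values(ascending=False).index
    col_order = pca.scores[pc].sort_values(ascending=False).index
    z = z.loc[row_order, col_order]
    lead = pd.Series([g in set(leading_edge) for g in z.index], index=z.index,
                     name="leading_edge")
    return z, lead
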