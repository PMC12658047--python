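from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from presig.gsea import (
    RankedList,
    enrichment_score,
    gsea_preranked,
    infer_direction,
    make_ranked,
    zscore_matrix,
)
from presig.io import GeneSet, GeneSetCollection


def brute_force_es(metrics, hits, weight=1):
    """Independent running-sum oracle, exact when given Fractions.

    Walks the ranked list once, accumulating hit increments and miss
    decrements step by step, and scans the whole running sum for the
    extremum.
    """
    n = len(metrics)
    w = [abs(m) ** weight if h else None for m, h in zip(metrics, hits)]
    total = sum(x for x in w if x is not None)
    nh = sum(hits)
    running = []
    s = Fraction(0)
    for i in range(n):
        if hits[i]:
            s = s + w[i] / total
        else:
            s = s - Fraction(1, n - nh)
        running.append(s)
    best = max(running, key=abs)
    # leftmost extremum by |value|
    for v in running:
        if abs(v) == abs(best):
            return v
    raise AssertionError


def _ranked(metrics, ids=None):
    ids = ids or [f"g{i + 1}" for i in range(len(metrics))]
    return RankedList(pd.Series(list(metrics), index=ids))


class TestEnrichmentScore:
    def test_top_hit(self):
        res = enrichment_score(_ranked([3.0, 2.0, 1.0]), {"g1"})
        assert res.es == 1.0
        assert res.leading_edge == ("g1",)
        assert res.peak == 0

    def test_bottom_hit(self):
        res = enrichment_score(_ranked([3.0, 2.0, 1.0]), {"g3"})
        assert res.es == -1.0
        assert res.leading_edge == ("g3",)

    def test_full_set(self):
        res = enrichment_score(_ranked([3.0, 2.0, 1.0]), {"g1", "g2", "g3"})
        assert res.es == pytest.approx(1.0, abs=1e-12)

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="empty intersection"):
            enrichment_score(_ranked([1.0]), {"zz"})

    def test_exact_oracle_small(self):
        """Exhaustive subset check at N=8 in exact rational arithmetic."""
        rng = np.random.default_rng(0)
        metrics = [Fraction(int(v), 100) for v in
                   sorted(rng.integers(-500, 500, 8))[::-1]]
        ranked = _ranked(metrics)
        ids = list(ranked.metric.index)
        for k in range(1, 8):
            for subset in combinations(range(8), k):
                hits = [i in subset for i in range(8)]
                want = brute_force_es(metrics, hits)
                got = enrichment_score(ranked, {ids[i] for i in subset}).es
                assert got == want  # exact equality of Fractions

    def test_reversal_antisymmetry(self, rng):
        metrics = np.sort(rng.normal(size=30))[::-1]
        ranked = _ranked(list(metrics))
        rev = _ranked(list(-metrics[::-1]), ids=[f"g{30 - i}" for i in range(30)])
        for members in ({"g3", "g7"}, {"g25", "g28", "g1"}):
            es1 = enrichment_score(ranked, members).es
            es2 = enrichment_score(rev, members).es
            assert es1 == pytest.approx(-es2, abs=1e-12)


class TestMakeRanked:
    def test_sorted_and_tie_broken_by_id(self):
        s = pd.Series({"b": 1.0, "a": 1.0, "c": 5.0})
        r = make_ranked(s)
        assert list(r.metric.index) == ["c", "a", "b"]

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError, match="descending"):
            RankedList(pd.Series([1.0, 2.0], index=["a", "b"]))


def _collection(sets):
    return GeneSetCollection([GeneSet(k, "", tuple(v)) for k, v in sets.items()])


class TestGseaPreranked:
    def test_p_floor(self, rng):
        metrics = np.sort(rng.normal(size=200))[::-1]
        ranked = _ranked(list(metrics))
        ids = list(ranked.metric.index)
        res = gsea_preranked(
            ranked, _collection({"TOP": ids[:10]}), n_perm=200, seed=1
        )
        assert res[0].p >= 1 / 201

    def test_planted_top_set_detected(self, rng):
        metrics = np.sort(rng.normal(size=2000))[::-1]
        ranked = _ranked(list(metrics))
        ids = list(ranked.metric.index)
        sets = {"TOP": ids[:20]}
        sets.update({f"R{j}": list(rng.choice(ids, 20, replace=False))
                     for j in range(10)})
        res = gsea_preranked(ranked, _collection(sets), n_perm=500, seed=2)
        by = {r.name: r for r in res}
        assert by["TOP"].nes > 0
        assert by["TOP"].padj < 0.05

    def test_size_filter_and_log(self, rng):
        metrics = np.sort(rng.normal(size=50))[::-1]
        ranked = _ranked(list(metrics))
        ids = list(ranked.metric.index)
        res = gsea_preranked(
            ranked, _collection({"TINY": ids[:2], "OK": ids[:10]}),
            n_perm=200, min_size=5, seed=0,
        )
        assert [r.name for r in res] == ["OK"]

    def test_leading_edge_subset_of_set(self, rng):
        metrics = np.sort(rng.normal(size=100))[::-1]
        ranked = _ranked(list(metrics))
        ids = list(ranked.metric.index)
        members = list(rng.choice(ids, 15, replace=False))
        res = gsea_preranked(ranked, _collection({"S": members}), n_perm=200, seed=0)
        assert set(res[0].leading_edge) <= set(members)

    def test_nes_sign_matches_es(self, rng):
        metrics = np.sort(rng.normal(size=300))[::-1]
        ranked = _ranked(list(metrics))
        ids = list(ranked.metric.index)
        sets = {"TOP": ids[:10], "BOT": ids[-10:]}
        res = gsea_preranked(ranked, _collection(sets), n_perm=300, seed=0)
        for r in res:
            assert np.sign(r.nes) == np.sign(r.es)

    def test_escalation_refines_floor_p(self, rng):
        metrics = np.sort(rng.normal(size=300))[::-1]
        ranked = _ranked(list(metrics))
        ids = list(ranked.metric.index)
        res = gsea_preranked(
            ranked, _collection({"TOP": ids[:10]}), n_perm=100, seed=0,
            n_perm_max=3200,
        )
        assert res[0].n_perm_used > 100

    def test_calibration_null_p_uniform(self, rng):
        """Random set under random rankings: raw p ~ Uniform(0, 1)."""
        ps = []
        for rep in range(300):
            metrics = np.sort(rng.normal(size=80))[::-1]
            ranked = _ranked(list(metrics))
            ids = list(ranked.metric.index)
            members = list(rng.choice(ids, 8, replace=False))
            res = gsea_preranked(
                ranked, _collection({"S": members}), n_perm=120, seed=rep
            )
            ps.append(res[0].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDirection:
    @pytest.mark.parametrize(
        "nes,r,expected",
        [
            (-2.83, -0.25, "Upregulated"),
            (-1.87, 0.3, "Downregulated"),
            (2.06, 0.3, "Upregulated"),
            (2.0, -0.4, "Downregulated"),
        ],
    )
    def test_rule(self, nes, r, expected):
        assert infer_direction(nes, r) == expected

    def test_zero_input_na(self):
        assert infer_direction(0.0, 0.5) == "n/a"
        assert infer_direction(1.2, 0.0) == "n/a"


class TestZscoreMatrix:
    @pytest.fixture()
    def setup(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(12, 8)) + rng.normal(size=(12, 1)),
            index=[f"G{i}" for i in range(12)],
            columns=[f"S{i}" for i in range(8)],
        )
        from presig.pca import run_pca

        pca = run_pca(expr)
        return expr, pca

    def test_rows_standardised(self, setup):
        expr, pca = setup
        z, _ = zscore_matrix(expr, list(expr.index), pca, "PC1")
        assert z.mean(axis=1).to_numpy() == pytest.approx(np.zeros(12), abs=1e-12)
        assert z.std(axis=1, ddof=1).to_numpy() == pytest.approx(np.ones(12))

    def test_column_order_by_score(self, setup):
        expr, pca = setup
        z, _ = zscore_matrix(expr, list(expr.index), pca, "PC1")
        want = pca.scores["PC1"].sort_values(ascending=False).index
        assert list(z.columns) == list(want)

    def test_constant_gene_zero_row(self, setup, rng):
        expr, pca = setup
        expr2 = expr.copy()
        expr2.loc["G0"] = 5.0
        z, _ = zscore_matrix(expr2, list(expr2.index), pca, "PC1")
        assert (z.loc["G0"] == 0).all()

    def test_planted_up_set_mean_z_higher_in_pe(self):
        from presig.normalize import estimate_spikein_size_factors, normalize_offset_log
        from presig.pca import run_pca
        from presig.simulate import PlantedPathway, SimulationConfig, generate_dataset

        cfg = SimulationConfig(
            n_samples_pe=12, n_samples_np=52, n_genes=600, n_spikeins=30,
            bias_sd=0.0, planted_pathways=(PlantedPathway("UP", 25, 1.2),),
            n_decoy_sets=0, seed=9,
        )
        cm, meta, sets, truth = generate_dataset(cfg)
        sf = estimate_spikein_size_factors(cm)
        expr = normalize_offset_log(cm, sf)
        expr = expr[expr.var(axis=1) > 0]
        pca = run_pca(expr)
        members = [g for g in truth.pathway_members["UP"] if g in expr.index]
        z, _ = zscore_matrix(expr, members, pca, "PC1")
        pe = meta.loc[z.columns, "condition"] == "PE"
        assert z.loc[:, pe.to_numpy()].mean().mean() > z.loc[:, ~pe.to_numpy()].mean().mean()
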