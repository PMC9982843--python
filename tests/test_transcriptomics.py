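"""PLS1 against sklearn and planted signals; permutation calibration;
GSEA against a brute-force running-sum oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corticograd.transcriptomics import (gsea, permutation_test_pls,
                                         plsr_spatial, rank_genes)


def _expr(values, symbols=None):
    g, n = np.asarray(values).shape
    symbols = symbols or [f"G{k:03d}" for k in range(g)]
    return pd.DataFrame(values, index=pd.Index(symbols, name="symbol"),
                        columns=range(1, n + 1))


class TestPlsrSpatial:
    def test_planted_gene_has_largest_weight(self, rng):
        # few background genes keep the rank-1 weight dilution small
        n, g = 80, 6
        y = rng.normal(size=n)
        expr = rng.normal(size=(g, n))
        expr[3] = 3.0 * y
        res = plsr_spatial(y, _expr(expr))
        assert np.argmax(np.abs(res.gene_weights)) == 3
        assert res.var_explained_pls1 > 0.9

    def test_orthogonal_map_explains_nothing(self, rng):
        n, g = 100, 50
        expr = rng.normal(size=(g, n))
        x = (expr - expr.mean(1, keepdims=True)) / expr.std(1, keepdims=True)
        y = rng.normal(size=n)
        # project the map out of every gene's span
        q, _ = np.linalg.qr(x.T)
        y = y - q @ (q.T @ y)
        res = plsr_spatial(y, _expr(expr))
        assert res.var_explained_pls1 < 0.05

    def test_single_noiseless_gene_is_univariate_regression(self, rng):
        # one informative gene (affine in the map) plus a constant gene,
        # which standardizes to zero: the rank-1 limit fits exactly
        n = 40
        y = rng.normal(size=n)
        expr = np.vstack([2.0 * y + 1.0, np.full(n, 3.0)])
        res = plsr_spatial(y, _expr(expr))
        assert res.var_explained_pls1 == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        n, g = 50, 12
        y = rng.normal(size=n)
        expr = rng.normal(size=(g, n))
        expr[3] += 1.5 * y
        res = plsr_spatial(y, _expr(expr))
        x = ((expr - expr.mean(1, keepdims=True)) / expr.std(1, keepdims=True)).T
        pls = PLSRegression(n_components=1, scale=False).fit(x, y - y.mean())
        w_sk = pls.x_weights_[:, 0]
        if np.dot(w_sk, res.gene_weights) < 0:
            w_sk = -w_sk
        assert res.gene_weights == pytest.approx(w_sk, abs=1e-8)
        r2 = 1.0 - np.sum((y - y.mean() - pls.predict(x).ravel()) ** 2) \
            / np.sum((y - y.mean()) ** 2)
        assert res.var_explained_pls1 == pytest.approx(r2, abs=1e-8)

    def test_invariant_to_gene_order_and_rescaling(self, rng):
        n, g = 40, 10
        y = rng.normal(size=n)
        expr = rng.normal(size=(g, n))
        base = plsr_spatial(y, _expr(expr))
        scaled = expr.copy()
        scaled[4] = 100.0 * scaled[4] - 7.0
        res = plsr_spatial(y, _expr(scaled))
        assert res.var_explained_pls1 == pytest.approx(
            base.var_explained_pls1, abs=1e-10)

    def test_constant_map_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            plsr_spatial(np.ones(10), _expr(rng.normal(size=(5, 10))))


class TestPermutationTest:
    def test_plus_one_lower_bound(self, rng):
        n = 30
        y = rng.normal(size=n)
        expr = rng.normal(size=(10, n))
        expr[0] = 5 * y
        p, _ = permutation_test_pls(y, _expr(expr), n_perm=99, seed=0)
        assert p >= 1 / 100

    def test_planted_signal_detected(self, rng):
        n, g = 100, 50
        y = np.sin(np.linspace(0, 4 * np.pi, n)) * 2 + rng.normal(size=n) * 0.5
        expr = rng.normal(size=(g, n))
        for k in range(8):
            expr[k] += rng.uniform(0.5, 1.5) * y
        p, _ = permutation_test_pls(y, _expr(expr), n_perm=199, seed=1)
        assert p <= 0.01

    def test_null_p_uniform_across_seeds(self):
        """Permutation p under a pure-noise map is uniform (KS check)."""
        rng = np.random.default_rng(2024)
        ps = []
        for seed in range(50):
            y = rng.normal(size=60)
            expr = rng.normal(size=(40, 60))
            p, _ = permutation_test_pls(y, _expr(expr), n_perm=99, seed=seed)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestRankGenes:
    def test_planted_gene_ranks_first(self, rng):
        n = 50
        y = rng.normal(size=n)
        expr = rng.normal(size=(20, n)) * 0.1
        expr[11] = 4.0 * y
        ranked = rank_genes(plsr_spatial(y, _expr(expr)))
        assert ranked.iloc[0]["symbol"] == "G011"

    def test_negated_map_reverses_ranking(self, rng):
        n = 40
        y = rng.normal(size=n)
        expr = rng.normal(size=(10, n))
        r1 = rank_genes(plsr_spatial(y, _expr(expr)))
        r2 = rank_genes(plsr_spatial(-y, _expr(expr)))
        assert list(r1["symbol"]) == list(r2["symbol"][::-1])

    def test_duplicate_weights_tie_break_lexicographic(self):
        from corticograd.transcriptomics import PlsResult
        pls = PlsResult(pls1_roi_scores=np.zeros(3),
                        gene_weights=np.array([0.5, 0.5, 1.0]),
                        gene_symbols=["B", "A", "C"],
                        var_explained_pls1=0.5)
        ranked = rank_genes(pls)
        assert list(ranked["symbol"]) == ["C", "A", "B"]


def _es_oracle(ranked, genes, exponent=1.0):
    """Brute-force running sum, step by step."""
    symbols = list(ranked["symbol"])
    scores = np.abs(ranked["score"].to_numpy()) ** exponent
    hits = set(genes) & set(symbols)
    nh = len(hits)
    n = len(symbols)
    if nh in (0, n):
        return 0.0
    wsum = sum(scores[i] for i, s in enumerate(symbols) if s in hits)
    run, best = 0.0, 0.0
    for i, s in enumerate(symbols):
        if s in hits:
            run += scores[i] / wsum
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    def _ranked(self, n, rng):
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.DataFrame({"symbol": [f"G{k:03d}" for k in range(n)],
                             "score": scores})

    def test_matches_brute_force_oracle_on_small_lists(self, rng):
        for trial in range(10):
            n = int(rng.integers(8, 20))
            ranked = self._ranked(n, rng)
            size = int(rng.integers(2, n - 1))
            genes = list(rng.choice(ranked["symbol"], size=size, replace=False))
            res = gsea(ranked, {"s": genes}, n_perm=99, seed=trial,
                       min_size=1, max_size=100)
            assert res.table.iloc[0]["es"] == pytest.approx(
                _es_oracle(ranked, genes), abs=1e-12)

    def test_top_block_set_strongly_enriched(self, rng):
        ranked = self._ranked(500, rng)
        top = list(ranked["symbol"][:20])
        res = gsea(ranked, {"top": top}, n_perm=999, seed=0)
        row = res.table.iloc[0]
        assert row["es"] > 0
        assert row["p"] <= 0.01

    def test_all_genes_set_has_zero_es(self, rng):
        ranked = self._ranked(30, rng)
        res = gsea(ranked, {"all": list(ranked["symbol"])}, n_perm=99,
                   seed=0, max_size=100)
        assert res.table.iloc[0]["es"] == 0.0

    def test_empty_intersection_skipped(self, rng):
        ranked = self._ranked(30, rng)
        res = gsea(ranked, {"alien": ["X1", "X2", "X3", "X4", "X5"]},
                   n_perm=99, seed=0)
        assert res.skipped == ["alien"]
        assert len(res.table) == 0

    def test_random_sets_calibrated(self, rng):
        """NES of random sets centres near +-1 and p-values are uniform."""
        ranked = self._ranked(300, rng)
        sets = {f"r{k}": list(rng.choice(ranked["symbol"], 30, replace=False))
                for k in range(60)}
        res = gsea(ranked, sets, n_perm=199, seed=5)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01
        assert np.mean(np.abs(res.table["nes"])) == pytest.approx(1.0, abs=0.25)

    def test_nes_sign_matches_es_and_q_at_least_p(self, rng):
        ranked = self._ranked(200, rng)
        sets = {f"r{k}": list(rng.choice(ranked["symbol"], 15, replace=False))
                for k in range(10)}
        sets["top"] = list(ranked["symbol"][:15])
        res = gsea(ranked, sets, n_perm=199, seed=2)
        t = res.table
        nonzero = t[t["es"] != 0]
        assert (np.sign(nonzero["nes"]) == np.sign(nonzero["es"])).all()
        assert (t["q"] >= t["p"] - 1e-12).all()
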