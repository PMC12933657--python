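"""d-separation basis sets, Fisher's C, CICc, model ranking and averaging."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import divpath as dp
from divpath.ppa import basis_set, model_set_report


def dsep_holds(dag, claim):
    """Oracle: verify a claim by networkx d-separation."""
    return nx.is_d_separator(dag, {claim.x}, {claim.y}, set(claim.given))


class TestBasisSet:
    def test_complete_dag_empty_basis(self):
        for k in (3, 4, 5):
            g = nx.DiGraph()
            nodes = [f"n{i}" for i in range(k)]
            g.add_edges_from((a, b) for i, a in enumerate(nodes)
                             for b in nodes[i + 1:])
            assert basis_set(g) == []

    def test_chain_single_claim(self, chain_dag):
        claims = basis_set(chain_dag, ["X", "Y", "Z"])
        assert len(claims) == 1
        (c,) = claims
        assert {c.x, c.y} == {"X", "Z"} and set(c.given) == {"Y"}

    def test_size_identity(self):
        """Basis size = C(k,2) - e for every model-set DAG."""
        ms = dp.build_rate_models()
        for mid, dag in ms.with_null().items():
            claims = basis_set(dag, ms.nodes)
            k, e = len(ms.nodes), dag.number_of_edges()
            assert len(claims) == k * (k - 1) // 2 - e, mid

    def test_claims_are_d_separations_random_dags(self):
        rng = np.random.default_rng(0)
        nodes = list("ABCDEF")
        for _ in range(50):
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            for i, a in enumerate(nodes):
                for b in nodes[i + 1:]:
                    if rng.random() < 0.35:
                        g.add_edge(a, b)
            for c in basis_set(g, nodes):
                assert dsep_holds(g, c)

    def test_cyclic_rejected(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError):
            basis_set(g)


class TestStatistics:
    def test_fisher_c_arithmetic(self):
        assert dp.fisher_c([]) == 0.0
        assert dp.fisher_c([1.0, 1.0]) == 0.0
        assert np.isclose(dp.fisher_c([0.05, 0.5]),
                          -2 * (np.log(0.05) + np.log(0.5)))
        assert np.isclose(dp.fisher_c([0.05, 0.5]), 7.378, atol=5e-4)

    def test_fisher_c_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dp.fisher_c([0.0, 0.5])

    def test_cicc_arithmetic(self):
        assert dp.cicc(0, 0, 100) == 0.0
        assert np.isclose(dp.cicc(10, 5, 20), 10 + 10 * 20 / 14)
        assert np.isclose(dp.cicc(3.0, 4, 10**9), 3.0 + 8.0, atol=1e-6)

    def test_cicc_overparameterized(self):
        with pytest.raises(ValueError):
            dp.cicc(1.0, 10, 11)


class TestFitModelSet:
    @pytest.fixture(scope="class")
    def chain_data(self, yule300, chain_dag):
        g = nx.DiGraph()
        g.add_edges_from([("X", "Y"), ("Y", "Z")])
        return dp.simulate_dag_data(yule300, g, {("X", "Y"): 0.7, ("Y", "Z"): 0.7},
                                    seed=31)

    def test_saturated_model_c_zero(self, yule50):
        rng = np.random.default_rng(1)
        from conftest import bm_tips_via_cholesky
        df = bm_tips_via_cholesky(yule50, 3, rng)
        df.columns = ["X", "Y", "Z"]
        sat = nx.DiGraph([("X", "Y"), ("X", "Z"), ("Y", "Z")])
        (fit,) = dp.fit_model_set({"sat": sat}, df, yule50)
        n, q = 50, 3 + 2
        assert fit.C == 0.0
        assert np.isclose(fit.CICc, 2 * q * n / (n - 1 - q))

    def test_chain_beats_direct_model(self, yule300, chain_data):
        chain = nx.DiGraph([("X", "Y"), ("Y", "Z")])
        direct = nx.DiGraph([("X", "Z")])
        for g in (chain, direct):
            g.add_nodes_from("XYZ")
        wins = 0
        for rep in range(10):
            df = dp.simulate_dag_data(yule300, chain,
                                      {("X", "Y"): 0.7, ("Y", "Z"): 0.7},
                                      seed=100 + rep)
            fits = dp.fit_model_set({"chain": chain, "direct": direct}, df,
                                    yule300, order=["X", "Y", "Z"])
            wins += fits[0].model_id == "chain"
        assert wins >= 9

    def test_duplicate_models_share_regressions(self, yule50):
        from conftest import bm_tips_via_cholesky
        df = bm_tips_via_cholesky(yule50, 3, np.random.default_rng(2))
        df.columns = ["X", "Y", "Z"]
        g = nx.DiGraph([("X", "Y")])
        g.add_nodes_from("XYZ")
        fits = dp.fit_model_set({"a": g, "b": g.copy()}, df, yule50,
                                order=["X", "Y", "Z"])
        assert np.isclose(fits[0].CICc, fits[1].CICc)
        cache = fits[0]._cache
        assert cache.n_unique < cache.requests  # dedup across models

    def test_missing_column_reported(self, yule50):
        df = pd.DataFrame({"X": np.arange(50.)}, index=yule50.tip_labels)
        g = nx.DiGraph([("X", "Y")])
        with pytest.raises(KeyError, match="Y"):
            dp.fit_model_set({"m": g}, df, yule50)

    def test_report_shape(self, yule50):
        from conftest import bm_tips_via_cholesky
        df = bm_tips_via_cholesky(yule50, 3, np.random.default_rng(3))
        df.columns = ["X", "Y", "Z"]
        g = nx.DiGraph([("X", "Y")])
        g.add_nodes_from("XYZ")
        fits = dp.fit_model_set({"m": g}, df, yule50, order=["X", "Y", "Z"])
        rpt = model_set_report(fits)
        assert list(rpt.columns) == ["model", "n_edges", "n_claims", "C", "q",
                                     "CICc", "delta_CICc", "weight"]


class TestAverageModels:
    def _fits_for(self, deltas, dags, table, tree, order):
        fits = dp.fit_model_set(dict(enumerate(dags)), table, tree, order=order)
        return fits

    def test_single_model_unchanged(self, yule300):
        g = nx.DiGraph([("X", "Y")])
        g.add_nodes_from("XY")
        df = dp.simulate_dag_data(yule300, g, {("X", "Y"): 0.6}, seed=41)
        fits = dp.fit_model_set({"m": g}, df, yule300, order=["X", "Y"])
        avg = dp.average_models(fits)
        direct = dp.fit_pgls(df, "Y", ["X"], yule300)
        assert np.isclose(avg.coef.loc["X", "Y"], direct.coef["X"], atol=1e-10)

    def test_equal_weight_zero_imputation(self):
        """Two equal-CICc models, path present once at beta=0.4 -> average 0.2."""

        class FakeCache:
            def fit(self, response, predictors):
                coef = pd.Series({p: 0.4 for p in predictors})
                se = pd.Series({p: 0.1 for p in predictors})
                return dp.PglsFit(response, tuple(predictors), coef, se,
                                  coef / se, se * 0 + .5, 10, 0.0, 1.0)

        withx = nx.DiGraph([("X", "Y")])
        withx.add_nodes_from("XY")
        without = nx.DiGraph()
        without.add_nodes_from("XY")
        fits = [
            dp.PathModelFit("a", withx, [], [], 0.0, 2, 50, 10.0),
            dp.PathModelFit("b", without, [], [], 0.0, 0, 50, 10.0),
        ]
        for f in fits:
            f._cache = FakeCache()
        avg = dp.average_models(fits, cutoff=2.0)
        assert np.isclose(avg.coef.loc["X", "Y"], 0.2)
        assert avg.weights == (0.5, 0.5)

    def test_full_average_shrinks_toward_zero(self, yule300):
        g = nx.DiGraph([("X", "Y")])
        g.add_nodes_from("XY")
        null = nx.DiGraph()
        null.add_nodes_from("XY")
        df = dp.simulate_dag_data(yule300, g, {("X", "Y"): 0.3}, seed=43)
        fits = dp.fit_model_set({"m": g, "null": null}, df, yule300,
                                order=["X", "Y"])
        if len([f for f in fits if f.delta <= 2.0]) == 2:
            avg = dp.average_models(fits)
            best = dp.fit_pgls(df, "Y", ["X"], yule300)
            assert abs(avg.coef.loc["X", "Y"]) < abs(best.coef["X"])

    def test_empty_cutoff_error(self):
        with pytest.raises(ValueError):
            dp.average_models([])
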