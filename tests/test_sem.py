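"""Standardization, stepwise AIC, d-separation, Fisher's C and effects."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamisd.sem import (
    PathModel,
    assemble_path_model,
    decompose_effects,
    directed_separation_tests,
    expand_categoricals,
    fishers_c,
    fit_submodel,
    standardize_table,
    stepwise_aic_select,
)


def exhaustive_aic_oracle(frame, response, candidates, forced):
    """All-subsets AIC minimum (independent of the stepwise search)."""
    y = frame[response].to_numpy(float)
    n = len(frame)
    best, best_aic = None, np.inf
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            cols = list(forced) + list(combo)
            X = np.column_stack([np.ones(n)] + [frame[c].to_numpy(float) for c in cols])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            aic = n * np.log(rss / n) + 2 * (X.shape[1] + 1)
            if aic < best_aic - 1e-12:
                best, best_aic = set(combo), aic
    return best


def make_frame(n, n_candidates, active, seed, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_candidates))
    y = X[:, : len(active)] @ np.asarray(active) + noise * rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(n_candidates)])
    df["y"] = y
    return df


class TestStandardize:
    def test_zscore_contract(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame({"a": rng.normal(3, 2, 400), "b": rng.uniform(0, 9, 400)})
        out, rep = standardize_table(raw)
        assert np.allclose(out.mean(), 0.0, atol=1e-12)
        assert np.allclose(out.std(ddof=0), 1.0, atol=1e-12)

    def test_skewed_with_zeros_gets_log1p(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(0, 1.5, 500))
        x[:25] = 0.0
        out, rep = standardize_table(pd.DataFrame({"crop": x}))
        assert rep.loc[0, "transform"] == "log1p"

    def test_skewed_positive_gets_log(self):
        rng = np.random.default_rng(2)
        out, rep = standardize_table(pd.DataFrame({"da": np.exp(rng.normal(0, 1.5, 500))}))
        assert rep.loc[0, "transform"] == "log"

    def test_symmetric_passthrough(self):
        rng = np.random.default_rng(3)
        out, rep = standardize_table(pd.DataFrame({"b": rng.normal(-1.4, 0.4, 500)}))
        assert rep.loc[0, "transform"] == "none"

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="flat"):
            standardize_table(pd.DataFrame({"flat": np.ones(10)}))

    def test_negative_skewed_column_rejected(self):
        x = np.exp(np.random.default_rng(4).normal(0, 2, 300)) - 5.0
        if abs(stats.skew(x)) > 1:
            with pytest.raises(ValueError, match="negative"):
                standardize_table(pd.DataFrame({"bad": x}))

    def test_categorical_passthrough(self):
        raw = pd.DataFrame({"a": np.random.default_rng(5).normal(size=12),
                            "eco": ["n", "s"] * 6})
        out, _ = standardize_table(raw, categorical=("eco",))
        assert list(out["eco"]) == ["n", "s"] * 6


class TestStepwise:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_minimum(self, seed):
        frame = make_frame(60, 10, [0.9, -0.7, 0.5], seed, noise=1.0)
        cands = [f"x{i}" for i in range(10)]
        sel = set(stepwise_aic_select(frame, "y", cands)) - set()
        oracle = exhaustive_aic_oracle(frame, "y", cands, [])
        assert sel == oracle

    def test_forced_terms_respected(self):
        frame = make_frame(80, 6, [0.8], 1)
        sel = stepwise_aic_select(frame, "y", [f"x{i}" for i in range(1, 6)],
                                  forced=["x0"])
        assert "x0" in sel

    def test_planted_strong_predictor_always_kept(self):
        kept = 0
        for seed in range(100):
            frame = make_frame(500, 5, [0.5], seed)
            sel = stepwise_aic_select(frame, "y", [f"x{i}" for i in range(5)])
            kept += "x0" in sel
        assert kept == 100

    def test_pure_noise_retention_matches_aic_theory(self):
        # AIC keeps a noise candidate with asymptotic probability
        # P(chi2_1 > 2) ~ 0.157; check the simulated rate against it
        kept = 0
        trials = 300
        for seed in range(trials):
            frame = make_frame(1000, 1, [], seed)  # y independent of x0
            kept += "x0" in stepwise_aic_select(frame, "y", ["x0"])
        rate = kept / trials
        expected = stats.chi2.sf(2, 1)
        assert abs(rate - expected) < 3 * np.sqrt(expected * (1 - expected) / trials)

    def test_disjointness_enforced(self):
        frame = make_frame(50, 3, [0.5], 0)
        with pytest.raises(ValueError):
            stepwise_aic_select(frame, "y", ["x0"], forced=["x0"])


def chain_frame(n, seed, bxm=0.5, bmy=0.4):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = bxm * x + rng.normal(size=n) * np.sqrt(1 - bxm**2)
    y = bmy * m + rng.normal(size=n) * np.sqrt(1 - bmy**2)
    return pd.DataFrame({"X": x, "M": m, "Y": y})


def chain_model(frame):
    return assemble_path_model(frame, [("M", [], ["X"]), ("Y", [], ["M"])])


class TestAssemble:
    def test_zero_noise_exact_recovery(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=(2, 200))
        m = 0.5 * x1 - 0.3 * x2
        y = 0.4 * m + 0.2 * x1
        frame = pd.DataFrame({"x1": x1, "x2": x2, "m": m, "y": y})
        model = assemble_path_model(
            frame, [("y", ["m", "x1", "x2"], []), ("m", ["x1", "x2"], [])]
        )
        assert model.edge_coef("m", "y") == pytest.approx(0.4, abs=1e-6)
        assert model.edge_coef("x1", "y") == pytest.approx(0.2, abs=1e-6)
        assert model.edge_coef("x1", "m") == pytest.approx(0.5, abs=1e-6)
        assert model.edge_coef("x2", "m") == pytest.approx(-0.3, abs=1e-6)
        assert model.edge_coef("x2", "y") is None

    def test_bivariate_coefficient_is_pearson_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = 0.6 * x + rng.normal(size=300)
        frame = pd.DataFrame({"x": (x - x.mean()) / x.std(),
                              "y": (y - y.mean()) / y.std()})
        model = assemble_path_model(frame, [("y", [], ["x"])])
        r = np.corrcoef(frame["x"], frame["y"])[0, 1]
        assert model.edge_coef("x", "y") == pytest.approx(r, abs=1e-10)

    def test_planted_sem_signs_and_magnitudes(self):
        # traits/flow-style three-layer system with moderate noise
        rng = np.random.default_rng(2)
        n = 500
        u = rng.normal(size=n)
        f = 0.5 * u + np.sqrt(1 - 0.25) * rng.normal(size=n)
        t = -0.45 * f + np.sqrt(1 - 0.45**2) * rng.normal(size=n)
        b = 0.55 * t + np.sqrt(1 - 0.55**2) * rng.normal(size=n)
        frame = pd.DataFrame({"u": u, "f": f, "t": t, "b": b})
        frame = (frame - frame.mean()) / frame.std()
        model = assemble_path_model(
            frame, [("b", ["t", "f", "u"], []), ("t", ["f", "u"], []), ("f", ["u"], [])]
        )
        for (a, c), planted in [(("t", "b"), 0.55), (("f", "t"), -0.45), (("u", "f"), 0.5)]:
            got = model.edge_coef(a, c)
            assert got is not None and np.sign(got) == np.sign(planted)
            assert abs(got - planted) < 0.10

    def test_cycle_detection(self):
        frame = chain_frame(50, 0)
        with pytest.raises(ValueError, match="cycle"):
            assemble_path_model(frame, [("M", [], ["Y"]), ("Y", [], ["M"])])


class TestDSeparation:
    def test_saturated_model_empty_basis(self):
        frame = chain_frame(100, 0)
        model = assemble_path_model(frame, [("M", [], ["X"]), ("Y", [], ["M", "X"])])
        assert directed_separation_tests(model, frame) == []

    def test_chain_has_single_claim(self):
        frame = chain_frame(100, 0)
        claims = directed_separation_tests(chain_model(frame), frame)
        assert len(claims) == 1
        assert claims[0][0].startswith("Y ~ X")

    def test_chain_claim_pvalues_uniform(self):
        # under the true chain the conditional-independence p-value is uniform
        ps = [directed_separation_tests(chain_model(f), f)[0][1]
              for f in (chain_frame(1000, s) for s in range(500))]
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.08

    def test_correlated_error_pair_excluded(self):
        frame = chain_frame(100, 0)
        model = assemble_path_model(frame, [("M", [], ["X"]), ("Y", [], ["M"])],
                                    correlated_error_pairs=[("Y", "X")])
        assert directed_separation_tests(model, frame) == []


class TestFishersC:
    def test_all_ones(self):
        assert fishers_c([1.0, 1.0]) == (0.0, 4, 1.0)

    def test_halves(self):
        c, df, p = fishers_c([0.5, 0.5])
        assert c == pytest.approx(2.77259, abs=1e-5)
        assert df == 4
        assert p == pytest.approx(0.596, abs=0.001)

    def test_empty_is_saturated(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            fishers_c([0.0, 0.5])

    def test_type_one_error_calibrated(self):
        # true chain, n = 200: Fisher's C should reject ~5% at alpha = .05
        rejections = 0
        for seed in range(500):
            frame = chain_frame(200, seed)
            model = chain_model(frame)
            claims = directed_separation_tests(model, frame)
            _, _, p = fishers_c([p for _, p in claims])
            rejections += p < 0.05
        assert 0.02 <= rejections / 500 <= 0.09


def random_dag_model(seed, max_nodes=8):
    rng = np.random.default_rng(seed)
    k = rng.integers(3, max_nodes + 1)
    names = [f"n{i}" for i in range(k)]
    edges = []
    for i in range(k):
        for j in range(i + 1, k):
            if rng.uniform() < 0.45:
                edges.append((names[i], names[j], float(rng.uniform(-1, 1)), 0.5))
    return PathModel(nodes=names, exogenous=[], edges=edges, correlated_errors=[],
                     submodels={}), names[-1]


def path_enumeration_oracle(model, response):
    g = nx.DiGraph()
    coef = {}
    for a, b, c, _ in model.edges:
        g.add_edge(a, b)
        coef[(a, b)] = c
    out = {}
    for u in model.nodes:
        if u == response:
            continue
        direct = coef.get((u, response), 0.0)
        total = 0.0
        if u in g and response in g:
            for path in nx.all_simple_paths(g, u, response):
                total += np.prod([coef[(path[i], path[i + 1])]
                                  for i in range(len(path) - 1)])
        out[u] = (direct, total - direct, total)
    return out


class TestEffects:
    def test_chain_product(self):
        m = PathModel(nodes=["X", "M", "b"], exogenous=["X"],
                      edges=[("X", "M", 0.5, 0.01), ("M", "b", 0.4, 0.01)],
                      correlated_errors=[], submodels={})
        eff = decompose_effects(m, "b").set_index("predictor")
        assert eff.loc["X", "direct"] == 0.0
        assert eff.loc["X", "indirect"] == pytest.approx(0.20)
        assert eff.loc["X", "total"] == pytest.approx(0.20)

    def test_direct_plus_indirect(self):
        m = PathModel(nodes=["X", "M", "b"], exogenous=["X"],
                      edges=[("X", "M", 0.5, 0.01), ("M", "b", 0.4, 0.01),
                             ("X", "b", 0.3, 0.01)],
                      correlated_errors=[], submodels={})
        eff = decompose_effects(m, "b").set_index("predictor")
        assert eff.loc["X", "total"] == pytest.approx(0.50)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration_oracle(self, seed):
        model, response = random_dag_model(seed)
        eff = decompose_effects(model, response).set_index("predictor")
        oracle = path_enumeration_oracle(model, response)
        for u, (d, i, t) in oracle.items():
            assert eff.loc[u, "direct"] == pytest.approx(d, abs=1e-12)
            assert eff.loc[u, "indirect"] == pytest.approx(i, abs=1e-10)
            assert eff.loc[u, "total"] == pytest.approx(t, abs=1e-10)
            assert abs(eff.loc[u, "total"]
                       - eff.loc[u, "direct"] - eff.loc[u, "indirect"]) < 1e-10


class TestCategoricalControls:
    def test_dummy_expansion_reference_level(self):
        df = pd.DataFrame({"eco": ["western", "northern", "central", "northern"],
                           "y": [1.0, 2.0, 3.0, 4.0]})
        out, groups = expand_categoricals(df, ("eco",))
        assert groups["eco"] == ["eco_northern", "eco_western"]
        assert "eco_central" not in out.columns  # alphabetical reference

    def test_categorical_claim_uses_partial_f(self):
        rng = np.random.default_rng(0)
        n = 200
        eco = rng.choice(["a", "b", "c"], size=n)
        y = rng.normal(size=n)
        frame = pd.DataFrame({"eco": eco, "y": y, "x": rng.normal(size=n)})
        frame, groups = expand_categoricals(frame, ("eco",))
        sm = fit_submodel(frame, "y", ["x", "eco"], groups)
        assert sm.r2 < 0.1  # noise fit; just exercises the grouped design
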