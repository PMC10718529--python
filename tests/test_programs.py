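"""Factor interpretation: associations, signatures, scoring, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from mcfa.programs import (
    FactorSignature,
    associate_factors,
    bh_adjust,
    enrich_hypergeometric,
    score_signatures,
    score_wmean,
    signature_jaccard,
    variance_partition_states,
    _eta_squared,
    _wmean_one,
)


def _scores(values, index=None):
    index = index or [f"s{i}" for i in range(len(values))]
    return pd.DataFrame({"Factor1": values}, index=index)


class TestAssociateFactors:
    def test_kruskal_hand_value(self):
        sc = _scores([1.0, 2.0, 3.0, 4.0])
        cov = pd.DataFrame({"grp": ["A", "A", "B", "B"]}, index=sc.index)
        out = associate_factors(sc, cov, kinds={"grp": "categorical"})
        assert out["statistic"].iloc[0] == pytest.approx(2.4)
        assert out["pval"].iloc[0] == pytest.approx(stats.chi2.sf(2.4, 1))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20)
        cov = pd.DataFrame({"g": ["A"] * 10 + ["B"] * 10},
                           index=[f"s{i}" for i in range(20)])
        h1 = associate_factors(_scores(x), cov)["statistic"].iloc[0]
        h2 = associate_factors(_scores(np.exp(x)), cov)["statistic"].iloc[0]
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 1000
        labels = np.array(["A"] * 10 + ["B"] * 10)
        for _ in range(n_sim):
            x = rng.standard_normal(20)
            p = stats.kruskal(x[labels == "A"], x[labels == "B"]).pvalue
            hits += p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_bh_step_up_hand_case(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=50))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()
        assert adj.max() <= 1.0

    def test_continuous_covariate_regression(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 20)
        y = 2 * x + 0.05 * rng.standard_normal(20)
        cov = pd.DataFrame({"ef": x}, index=[f"s{i}" for i in range(20)])
        out = associate_factors(_scores(y), cov, kinds={"ef": "continuous"})
        assert out["pval"].iloc[0] < 1e-6
        assert out["kind"].iloc[0] == "continuous"

    def test_constant_covariate_skipped(self):
        sc = _scores([1.0, 2.0, 3.0, 4.0])
        cov = pd.DataFrame({"c": [1, 1, 1, 1]}, index=sc.index)
        with pytest.warns(UserWarning, match="constant"):
            out = associate_factors(sc, cov)
        assert out.empty


class TestSignatures:
    class _FakeModel:
        view_names = ["ct"]
        K = 2

        def __init__(self, weights):
            self._w = weights

        def weights(self, view):
            return self._w

    def test_threshold_and_sign_split(self):
        w = pd.DataFrame({"Factor1": [0.05, 0.5, -0.3]}, index=["g1", "g2", "g3"])
        w["Factor2"] = 0.0
        from mcfa.programs import extract_signatures
        sigs = extract_signatures(self._FakeModel(w), 0, threshold=0.1)
        by_sign = {s.sign: s for s in sigs}
        assert dict(by_sign["positive"].weights) == {"g2": 0.5}
        assert dict(by_sign["negative"].weights) == {"g3": -0.3}

    def test_partition_counts(self):
        rng = np.random.default_rng(8)
        w = pd.DataFrame({"Factor1": rng.standard_normal(100)},
                         index=[f"g{i}" for i in range(100)])
        w["Factor2"] = 0.0
        from mcfa.programs import extract_signatures
        sigs = extract_signatures(self._FakeModel(w), 0, threshold=0.1)
        total = sum(len(s) for s in sigs)
        assert total == int((w["Factor1"].abs() >= 0.1).sum())
        genes = [g for s in sigs for g in s.genes]
        assert len(genes) == len(set(genes))  # each gene in exactly one sign

    def test_out_of_range_factor(self):
        w = pd.DataFrame({"Factor1": [1.0]}, index=["g"])
        from mcfa.programs import extract_signatures
        with pytest.raises(IndexError):
            extract_signatures(self._FakeModel(w), 5)

    def test_sign_consistency_enforced(self):
        with pytest.raises(ValueError):
            FactorSignature("ct", 0, "positive", pd.Series({"g": -1.0}), 0.1)


class TestScoreWmean:
    def test_raw_score_closed_form(self):
        X = pd.DataFrame([[3.0, 1.0, 0.0]], index=["s"], columns=["g1", "g2", "g3"])
        s, _, _ = _wmean_one(X.to_numpy(), X.columns,
                             pd.Series({"g1": 2.0, "g2": -1.0}), 10, 0)
        assert s[0] == pytest.approx(5 / 3)

    def test_equal_weights_reduce_to_mean(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((5, 20)),
                         columns=[f"g{i}" for i in range(20)])
        sig = FactorSignature("ct", 0, "positive",
                              pd.Series(1.0, index=[f"g{i}" for i in range(6)]), 0.1)
        res = score_wmean(X, sig, n_perm=10, seed=0)
        np.testing.assert_allclose(
            res.scores.iloc[:, 0].to_numpy(),
            X.iloc[:, :6].mean(axis=1).to_numpy(), atol=1e-12)

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((500, 300)),
                         columns=[f"g{i}" for i in range(300)])
        genes = rng.choice(300, 50, replace=False)
        sig = FactorSignature(
            "ct", 0, "positive",
            pd.Series(rng.uniform(0.2, 2.0, 50), index=[f"g{i}" for i in genes]), 0.1)
        res = score_wmean(X, sig, n_perm=1000, seed=11)
        z = res.z.iloc[:, 0]
        assert -0.1 < z.mean() < 0.1
        assert 0.85 < z.std() < 1.15

    def test_z_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((20, 50)),
                         columns=[f"g{i}" for i in range(50)])
        w = pd.Series(rng.uniform(0.2, 1.0, 10), index=[f"g{i}" for i in range(10)])
        s1 = FactorSignature("ct", 0, "positive", w, 0.1)
        s2 = FactorSignature("ct", 0, "positive", 7.5 * w, 0.1)
        z1 = score_wmean(X, s1, n_perm=100, seed=3).z
        z2 = score_wmean(X, s2, n_perm=100, seed=3).z
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_degenerate_null_flagged(self):
        X = pd.DataFrame(np.zeros((3, 10)), columns=[f"g{i}" for i in range(10)])
        sig = FactorSignature("ct", 0, "positive",
                              pd.Series(1.0, index=["g0", "g1"]), 0.1)
        res = score_wmean(X, sig, n_perm=20, seed=0)
        assert res.degenerate.all().all()
        assert (res.z == 0).all().all()

    def test_empty_effective_signature_errors(self):
        X = pd.DataFrame([[1.0]], columns=["g0"])
        sig = FactorSignature("ct", 0, "positive", pd.Series({"absent": 1.0}), 0.1)
        with pytest.raises(ValueError, match="empty"), pytest.warns(UserWarning):
            score_wmean(X, sig, n_perm=10, seed=0)

    def test_batch_matches_single(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((8, 40)),
                         columns=[f"g{i}" for i in range(40)])
        sigs = [
            FactorSignature("a", 0, "positive",
                            pd.Series(1.0, index=[f"g{i}" for i in range(5)]), 0.1),
            FactorSignature("b", 0, "negative",
                            pd.Series(-1.0, index=[f"g{i}" for i in range(6, 12)]), 0.1),
        ]
        batch = score_signatures(X, sigs, n_perm=50, seed=21)
        for sig in sigs:
            solo = score_wmean(X, sig, n_perm=50, seed=21)
            np.testing.assert_array_equal(batch.z[sig.name].to_numpy(),
                                          solo.z[sig.name].to_numpy())


class TestHypergeometric:
    def test_worked_example(self):
        out = enrich_hypergeometric(
            {"a", "b", "c", "d"},
            {"st": {"a", "b", "c", "d", "e"}},
            {f"x{i}" for i in range(5)} | {"a", "b", "c", "d", "e"},
        )
        assert out["pval"].iloc[0] == pytest.approx(5 / 210)

    def test_zero_overlap_p_one(self):
        out = enrich_hypergeometric({"a"}, {"st": {"b"}}, {"a", "b", "c"})
        assert out["pval"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        # brute force over all C(N, n) draws for small universes
        from itertools import combinations
        for trial in range(5):
            N = int(rng.integers(8, 16))
            universe = [f"g{i}" for i in range(N)]
            markers = set(rng.choice(universe, size=int(rng.integers(2, N - 1)),
                                     replace=False))
            n_sig = int(rng.integers(2, N - 1))
            sig = set(rng.choice(universe, size=n_sig, replace=False))
            k_obs = len(sig & markers)
            count = sum(1 for draw in combinations(universe, n_sig)
                        if len(set(draw) & markers) >= k_obs)
            expected = count / comb(N, n_sig, exact=True)
            out = enrich_hypergeometric(sig, {"st": markers}, universe)
            assert out["pval"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            enrich_hypergeometric({"a"}, {"s": {"a"}}, set())


class TestVariancePartition:
    def test_eta_squared_hand_sums(self):
        eta, _ = _eta_squared(np.array([1.0, 2, 3, 4]), np.array(list("AABB")))
        assert eta == pytest.approx(0.8)
        eta0, _ = _eta_squared(np.array([1.0, 2, 1, 2]), np.array(list("AABB")))
        assert eta0 == pytest.approx(0.0)

    def test_log_ratio_value(self):
        rng = np.random.default_rng(6)
        genes = ["g0"]
        # condition explains more variance than state for g0
        cond = pd.DataFrame({"g0": [0, 0.1, 2.0, 2.1, 0.05, 1.95]},
                            index=[f"s{i}" for i in range(6)])
        cl = pd.Series(["A", "A", "B", "B", "A", "B"], index=cond.index)
        state = pd.DataFrame({"g0": rng.standard_normal(8) * 1.0},
                             index=[f"p{i}" for i in range(8)])
        sl = pd.Series(["x"] * 4 + ["y"] * 4, index=state.index)
        res = variance_partition_states(cond, cl, state, sl, genes)
        row = res.per_gene.iloc[0]
        expect = np.log2(row["eta2_cond"] / row["eta2_state"])
        assert row["log2_ratio"] == pytest.approx(expect)
        assert 0 <= row["eta2_cond"] <= 1 and 0 <= row["eta2_state"] <= 1

    def test_ratio_is_two_for_08_vs_02(self):
        assert np.log2(0.8 / 0.2) == pytest.approx(2.0)

    def test_requires_replicated_groups(self):
        cond = pd.DataFrame({"g0": [1.0, 2.0]}, index=["a", "b"])
        cl = pd.Series(["A", "B"], index=cond.index)
        with pytest.raises(ValueError):
            variance_partition_states(cond, cl, cond, cl, ["g0"])


class TestJaccard:
    def test_values(self):
        out = signature_jaccard({
            "a": {"a", "b", "c"}, "b": {"b", "c", "d"}, "c": {"x"},
        })
        assert out.loc["a", "b"] == pytest.approx(0.5)
        assert out.loc["a", "a"] == 1.0
        assert out.loc["a", "c"] == 0.0
        pd.testing.assert_frame_equal(out, out.T)
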