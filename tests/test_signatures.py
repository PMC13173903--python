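import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scstates.signatures import (
    assign_states,
    hypergeom_enrich,
    metastatic_coexpression,
    overlap_coefficient,
    positive_fraction,
    pseudobulk_signature,
    score_gene_set,
    score_pseudobulk,
)


class TestOverlapCoefficient:
    def test_self(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_hand_two_thirds(self):
        assert overlap_coefficient({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(2 / 3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})

    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=15),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=15),
    )
    @settings(max_examples=60, deadline=None)
    def test_properties(self, a, b):
        oc = overlap_coefficient(a, b)
        assert 0.0 <= oc <= 1.0
        assert oc == overlap_coefficient(b, a)
        if a <= b:
            assert oc == 1.0


def hypergeom_tail_oracle(k, N, K, n):
    """Exhaustive enumeration of the hypergeometric upper tail."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / total
        for i in range(k, min(n, K) + 1)
    )


class TestHypergeomEnrich:
    def test_zero_overlap_p_one(self):
        out = hypergeom_enrich(["m1", "m2", "m3"], {"s": ["x1", "x2", "x3"]}, 100)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_example(self):
        markers = [f"m{i}" for i in range(5)]
        gene_set = markers[:3] + ["x1", "x2"]
        out = hypergeom_enrich(markers, {"s": gene_set}, 20)
        assert out["k"].iloc[0] == 3
        assert out["p"].iloc[0] == pytest.approx(0.07262, abs=5e-5)

    def test_full_overlap_extreme(self):
        markers = ["a", "b", "c"]
        out = hypergeom_enrich(markers, {"s": markers}, 10)
        assert out["p"].iloc[0] == pytest.approx(1 / math.comb(10, 3), abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(3, min(N, 20)))
            n = int(rng.integers(1, N // 2))
            universe = [f"g{i}" for i in range(N)]
            markers = list(rng.choice(universe, size=n, replace=False))
            gene_set = list(rng.choice(universe, size=K, replace=False))
            out = hypergeom_enrich(markers, {"s": gene_set}, N)
            k = len(set(markers) & set(gene_set))
            assert out["p"].iloc[0] == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), abs=1e-12
            )

    def test_size_filter(self):
        sets = {"tiny": ["a"], "ok": ["a", "b", "c"], "huge": [f"g{i}" for i in range(600)]}
        out = hypergeom_enrich(["a", "b"], sets, 1000)
        assert list(out["set"]) == ["ok"]

    def test_significance_rule(self):
        markers = [f"m{i}" for i in range(10)]
        sets = {"hit": markers[:5], "miss": ["x1", "x2", "x3"]}
        out = hypergeom_enrich(markers, sets, 2000).set_index("set")
        assert bool(out.loc["hit", "significant"])
        assert not bool(out.loc["miss", "significant"])

    def test_set_bigger_than_universe(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["a"], {"s": [f"g{i}" for i in range(30)]}, 10)


class TestScoreGeneSet:
    def test_top_ranked_positive(self):
        expr = pd.DataFrame(
            [[10.0, 9.0, 1.0, 0.5, 0.2, 0.1]],
            columns=["s1", "s2", "n1", "n2", "n3", "n4"],
        )
        score = score_gene_set(expr, ["s1", "s2"])
        assert score.iloc[0] > 0.5

    def test_bottom_ranked_negative(self):
        expr = pd.DataFrame(
            [[10.0, 9.0, 8.0, 7.0, 0.2, 0.1]],
            columns=["n1", "n2", "n3", "n4", "s1", "s2"],
        )
        score = score_gene_set(expr, ["s1", "s2"])
        assert score.iloc[0] < -0.5

    def test_random_set_median_near_zero(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(2000, 50)), columns=[f"g{i}" for i in range(50)]
        )
        score = score_gene_set(expr, ["g3", "g17", "g31", "g44"])
        assert abs(score.median()) < 0.05

    def test_monotone_in_set_expression(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(50, 30)), columns=[f"g{i}" for i in range(30)]
        )
        gene_set = ["g1", "g2", "g3"]
        s0 = score_gene_set(expr, gene_set)
        for bump in [0.5, 1.0, 3.0]:
            expr2 = expr.copy()
            expr2[gene_set] += bump
            s1 = score_gene_set(expr2, gene_set)
            assert (s1 >= s0 - 1e-12).all()
            s0 = s1

    def test_mean_z_method(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(100, 10)), columns=[f"g{i}" for i in range(10)]
        )
        expr.iloc[0, [0, 1]] += 5
        score = score_gene_set(expr, ["g0", "g1"], method="mean-z")
        assert score.iloc[0] > 2

    def test_too_few_genes(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            score_gene_set(expr, ["a"])


class TestAssignStates:
    def test_all_negative_unassigned(self):
        scores = pd.DataFrame({"MC0": [-0.2], "MC1": [-0.1]})
        assert assign_states(scores).iloc[0] == "unassigned"

    def test_argmax_positive(self):
        scores = pd.DataFrame({"MC0": [0.3], "MC1": [0.1]})
        assert assign_states(scores).iloc[0] == "MC0"

    def test_permutation_equivariant(self, rng):
        scores = pd.DataFrame(rng.normal(size=(50, 3)), columns=["MC0", "MC1", "MC2"])
        s1 = assign_states(scores)
        s2 = assign_states(scores[["MC2", "MC0", "MC1"]])
        ties = (scores.to_numpy() == scores.max(axis=1).to_numpy()[:, None]).sum(axis=1) > 1
        assert (s1[~ties] == s2[~ties]).all()

    def test_tie_breaks_to_earliest_column(self):
        scores = pd.DataFrame({"MC1": [0.5], "MC0": [0.5]})
        assert assign_states(scores).iloc[0] == "MC1"


class TestPositiveFraction:
    def test_all_negative(self):
        scores = pd.Series([-1.0, -2.0, -0.5, -1.5])
        groups = pd.Series(["a", "a", "b", "b"])
        frac, p = positive_fraction(scores, groups)
        assert (frac["fraction"] == 0).all()

    def test_identical_groups_p_one(self):
        scores = pd.Series([1.0, -1.0, 2.0, 1.0, -1.0, 2.0])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        units = pd.Series(["u1", "u2", "u3", "u1", "u2", "u3"])
        _, p = positive_fraction(scores, groups, units=units, paired=True)
        assert p == pytest.approx(1.0)

    def test_planted_paired_power(self, rng):
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            pre = np.clip(r.normal(0.6, 0.12, size=10), 0, 1)
            post = np.clip(r.normal(0.3, 0.12, size=10), 0, 1)
            rows = []
            for u in range(10):
                for grp, f in (("pre", pre[u]), ("post", post[u])):
                    for c in range(20):
                        rows.append({"score": 1.0 if c < round(f * 20) else -1.0,
                                     "group": grp, "unit": f"u{u}"})
            df = pd.DataFrame(rows)
            _, p = positive_fraction(df["score"], df["group"], units=df["unit"], paired=True)
            hits += p < 0.05
        assert hits / n_rep > 0.8

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            positive_fraction(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


class TestPseudobulkRecipes:
    def test_rps_scaled_negsum_toy(self):
        pb = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["MC0|s1"],
                          columns=["RIF1", "PARI", "RAD51", "XRCC5"])
        assert score_pseudobulk(pb, "scaled-negsum").iloc[0] == pytest.approx(-4.0)

    def test_mean_recipe_toy(self):
        pb = pd.DataFrame([[2.0, 4.0]], index=["MC0|s1"], columns=["a", "b"])
        assert score_pseudobulk(pb, "mean").iloc[0] == pytest.approx(3.0)

    def test_pc1_recovers_planted_factor(self, rng):
        factor = rng.normal(size=20)
        loadings = np.abs(rng.normal(size=10)) + 0.2
        pb = pd.DataFrame(
            np.outer(factor, loadings) + rng.normal(0, 0.01, size=(20, 10))
        )
        got = score_pseudobulk(pb, "pc1")
        assert abs(np.corrcoef(got, factor)[0, 1]) > 0.99

    def test_pc1_sign_anchored(self, rng):
        factor = rng.normal(size=20)
        loadings = np.abs(rng.normal(size=10)) + 0.2
        pb = pd.DataFrame(np.outer(factor, loadings))
        got = score_pseudobulk(pb, "pc1")
        assert np.corrcoef(got, pb.mean(axis=1))[0, 1] > 0

    def test_full_pseudobulk_path(self, rng):
        cells = [f"c{i}" for i in range(30)]
        lognorm = pd.DataFrame(
            rng.lognormal(0, 0.3, size=(30, 5)), index=cells,
            columns=["a", "b", "c", "d", "e"],
        )
        groups = pd.Series(["MC0"] * 15 + ["MC1"] * 15, index=cells)
        out = pseudobulk_signature(lognorm, ["a", "b"], "mean", groups)
        manual = lognorm.groupby(groups)[["a", "b"]].mean().mean(axis=1)
        pd.testing.assert_series_equal(out, manual, check_names=False)

    def test_rps_missing_gene_raises(self, rng):
        lognorm = pd.DataFrame(rng.random((10, 3)), columns=["RIF1", "PARI", "RAD51"])
        groups = pd.Series(["g"] * 10)
        with pytest.raises(ValueError, match="XRCC5"):
            pseudobulk_signature(lognorm, ["RIF1", "PARI", "RAD51", "XRCC5"],
                                 "scaled-negsum", groups)


class TestMetastaticCoexpression:
    def test_equal_unit_scores(self):
        x = pd.Series([1.0, 1.0, 1.0])
        raw, _ = metastatic_coexpression(x, x)
        assert raw.iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_zero_component(self):
        raw, _ = metastatic_coexpression(pd.Series([0.0, 1.0]), pd.Series([1.0, 1.0]))
        assert raw.iloc[0] == 0.0

    def test_hand_scaling(self):
        x = pd.Series([1.0, 0.0, 2.0])
        y = pd.Series([1.0, 1.0, 2.0])
        raw, scaled = metastatic_coexpression(x, y)
        np.testing.assert_allclose(raw, [0.70710678, 0.0, 1.41421356], atol=1e-8)
        np.testing.assert_allclose(scaled, [0.5, 0.0, 1.0], atol=1e-8)

    def test_both_zero_warns(self):
        with pytest.warns(UserWarning, match="x = y = 0"):
            raw, _ = metastatic_coexpression(pd.Series([0.0, 1.0]), pd.Series([0.0, 1.0]))
        assert raw.iloc[0] == 0.0
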