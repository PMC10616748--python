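"""Surrogate variables, rank product, fold change, signatures."""

import itertools

import numpy as np
import pandas as pd
import pytest

from premodmir import (
    estimate_surrogate_variables,
    fold_change_ct,
    intersect_signatures,
    normalize_mirna_name,
    rank_product_test,
    remove_unwanted_variation,
    significant_features,
)
from premodmir.de_analysis import _bh


def _expr(Y):
    df = pd.DataFrame(np.asarray(Y, dtype=float))
    df.index = [f"f{i}" for i in range(df.shape[0])]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return df


GROUPS_20V20 = ["case"] * 20 + ["control"] * 20


class TestNameNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("hsa-miR-885-5p", "mir-885-5p"),
            ("hsa‐miR‐885‐5p", "mir-885-5p"),  # unicode hyphens
            ("MIR-885-5P", "mir-885-5p"),
            ("hsa-miR-1244", "mir-1244"),
        ],
    )
    def test_equivalent_spellings_collapse(self, raw, expected):
        assert normalize_mirna_name(raw) == expected

    def test_arm_suffix_preserved(self):
        assert normalize_mirna_name("hsa-miR-31-5p") != normalize_mirna_name("hsa-miR-31-3p")


class TestSurrogateVariables:
    def test_planted_factor_recovered(self):
        r = np.random.default_rng(1)
        n = 40
        factor = r.standard_normal(n)
        load = r.standard_normal(100)
        Y = 25 + 2.0 * np.outer(load, factor) + 0.3 * r.standard_normal((100, n))
        svs = estimate_surrogate_variables(_expr(Y), GROUPS_20V20, seed=0)
        assert svs.n_sv >= 1
        cor = np.corrcoef(svs.scores.iloc[:, 0], factor)[0, 1]
        assert abs(cor) > 0.9

    def test_pure_noise_yields_zero_svs_most_seeds(self):
        zeros = 0
        n_seeds = 50
        for seed in range(n_seeds):
            r = np.random.default_rng(10_000 + seed)
            Y = 25 + 0.5 * r.standard_normal((100, 40))
            svs = estimate_surrogate_variables(_expr(Y), GROUPS_20V20, seed=0, n_perm=50)
            zeros += svs.n_sv == 0
        assert zeros >= 0.9 * n_seeds

    def test_fixed_n_sv_returns_exactly_that_many(self):
        r = np.random.default_rng(2)
        Y = 25 + r.standard_normal((60, 40))
        svs = estimate_surrogate_variables(_expr(Y), GROUPS_20V20, n_sv=8, seed=0)
        assert svs.n_sv == 8

    def test_sv_scores_orthogonal(self):
        r = np.random.default_rng(3)
        Y = 25 + r.standard_normal((60, 40)) + np.outer(r.standard_normal(60), r.standard_normal(40))
        svs = estimate_surrogate_variables(_expr(Y), GROUPS_20V20, n_sv=4, seed=0)
        gram = svs.scores.to_numpy().T @ svs.scores.to_numpy()
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_too_few_samples_raises(self):
        Y = _expr(np.ones((5, 3)) + np.arange(15).reshape(5, 3))
        prot = pd.DataFrame(
            {"x1": [0.0, 1.0, 2.0], "x2": [1.0, 0.0, 2.0]}, index=Y.columns
        )
        with pytest.raises(ValueError, match="few samples"):
            estimate_surrogate_variables(Y, ["a", "b", "a"], protect=prot, seed=0)


class TestRemoveUnwantedVariation:
    def test_no_svs_no_nuisance_is_identity(self):
        r = np.random.default_rng(4)
        Y = _expr(25 + r.standard_normal((30, 20)))
        out = remove_unwanted_variation(Y, None)
        pd.testing.assert_frame_equal(out, Y)

    def test_planted_batch_removed(self):
        r = np.random.default_rng(5)
        n = 40
        batch = r.standard_normal(n)
        load = r.standard_normal(150)
        Y = 25 + 1.5 * np.outer(load, batch) + 0.3 * r.standard_normal((150, n))
        expr = _expr(Y)
        svs = estimate_surrogate_variables(expr, GROUPS_20V20, seed=0)
        adj = remove_unwanted_variation(expr, svs, primary=GROUPS_20V20)
        cors = [abs(np.corrcoef(adj.iloc[i], batch)[0, 1]) for i in range(150)]
        assert np.median(cors) < 0.1

    def test_planted_group_effect_preserved(self):
        effect = 1.0
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(200 + seed)
            n = 40
            batch = r.standard_normal(n)
            Y = 25 + 1.0 * np.outer(r.standard_normal(100), batch) + 0.4 * r.standard_normal((100, n))
            Y[:10, :20] -= effect  # planted case shift on Ct scale
            expr = _expr(Y)
            svs = estimate_surrogate_variables(expr, GROUPS_20V20, seed=0)
            adj = remove_unwanted_variation(expr, svs, primary=GROUPS_20V20)
            diffs.append(np.mean(adj.iloc[:10, :20].to_numpy()) - np.mean(adj.iloc[:10, 20:].to_numpy()))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - (-effect)) < 3 * se + 0.05

    def test_collinear_design_raises(self):
        r = np.random.default_rng(6)
        Y = _expr(25 + r.standard_normal((10, 12)))
        prot = pd.DataFrame(
            {"x1": np.arange(12.0), "x2": 2 * np.arange(12.0)}, index=Y.columns
        )
        with pytest.raises(ValueError, match="collinear"):
            remove_unwanted_variation(Y, None, protect=prot)


def brute_force_rank_products(expr, pairs):
    """Independent oracle: per-feature geometric-mean ranks over explicit
    case-control pairs, by direct sorting."""
    Y = expr.to_numpy()
    n_feat = Y.shape[0]
    up = np.ones(n_feat)
    down = np.ones(n_feat)
    cols = {s: k for k, s in enumerate(expr.columns)}
    for ci, tj in pairs:
        d = Y[:, cols[ci]] - Y[:, cols[tj]]
        order_desc = sorted(range(n_feat), key=lambda f: -d[f])
        r_up = np.empty(n_feat)
        for pos, f in enumerate(order_desc, start=1):
            r_up[f] = pos
        r_down = n_feat + 1 - r_up  # no ties in continuous data
        up *= r_up
        down *= r_down
    k = len(pairs)
    return up ** (1.0 / k), down ** (1.0 / k)


class TestRankProduct:
    def test_feature_always_ranked_first_has_rp_one(self):
        Y = np.ones((4, 8)) * 25
        Y[0, :4] += 5  # feature 0 maximally up in every comparison
        de = rank_product_test(_expr(Y), ["case"] * 4 + ["control"] * 4, n_perm=50, seed=0)
        assert de.table["rp_up"].iloc[0] == pytest.approx(1.0)

    def test_geometric_mean_of_ranks_two_and_eight(self):
        # feature ranked 2nd and 8th among 10 in two comparisons -> rp = 4
        assert np.sqrt(2 * 8) == pytest.approx(4.0)
        rng = np.random.default_rng(7)
        n_feat = 10
        base = rng.normal(0, 0.01, (n_feat, 4))
        # comparison 1 = (s0, s2), comparison 2 = (s1, s3) under disjoint pairing
        de = rank_product_test(
            _expr(base), ["case", "case", "control", "control"], n_perm=50, seed=0
        )
        up, down = brute_force_rank_products(
            _expr(base), de.comparisons
        )
        assert np.allclose(de.table["rp_up"].to_numpy(), up)
        assert np.allclose(de.table["rp_down"].to_numpy(), down)

    def test_matches_brute_force_on_toy_matrix(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(25, 2, size=(4, 4))
        de = rank_product_test(_expr(Y), ["case", "case", "control", "control"], n_perm=100, seed=3)
        up, down = brute_force_rank_products(_expr(Y), de.comparisons)
        assert np.allclose(de.table["rp_up"], up)
        assert np.allclose(de.table["rp_down"], down)

    def test_pfp_matches_exhaustive_permutation_oracle(self):
        """pfp within Monte-Carlo error of the closed-form expected-rank
        oracle: with independent comparisons, a null feature's ranks are
        iid uniform on {1..F}, so E[#null <= x] enumerates exactly."""
        rng = np.random.default_rng(9)
        n_feat = 4
        Y = rng.normal(25, 2, size=(n_feat, 4))
        expr = _expr(Y)
        de = rank_product_test(expr, ["case", "case", "control", "control"], n_perm=5000, seed=1)
        up, _ = brute_force_rank_products(expr, de.comparisons)
        k = len(de.comparisons)
        # enumerate all rank combinations for one feature
        null_rps = np.array(
            [np.prod(c) ** (1 / k) for c in itertools.product(range(1, n_feat + 1), repeat=k)]
        )
        order = np.argsort(up, kind="stable")
        pfp_oracle = np.empty(n_feat)
        for r, f in enumerate(order, start=1):
            e_fp = n_feat * np.mean(null_rps <= up[f] + 1e-12)
            pfp_oracle[f] = e_fp / r
        # same step-up monotonization as the implementation
        pfp_oracle_sorted = pfp_oracle[order]
        pfp_oracle_sorted = np.minimum.accumulate(pfp_oracle_sorted[::-1])[::-1]
        pfp_oracle[order] = np.clip(pfp_oracle_sorted, 0, 1)
        mc_se = 3 * np.sqrt(0.25 / 5000) * n_feat
        assert np.all(np.abs(de.table["pfp_up"].to_numpy() - pfp_oracle) < mc_se + 0.02)

    def test_direction_symmetry_up_down(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(25, 1, size=(15, 12))
        groups = ["case"] * 6 + ["control"] * 6
        de_pos = rank_product_test(_expr(Y), groups, n_perm=50, seed=5)
        de_neg = rank_product_test(_expr(-Y), groups, n_perm=50, seed=5)
        assert np.allclose(de_pos.table["rp_up"], de_neg.table["rp_down"])
        assert np.allclose(de_pos.table["rp_down"], de_neg.table["rp_up"])

    def test_pfp_monotone_along_rank_ordering(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(25, 1, size=(50, 20))
        de = rank_product_test(_expr(Y), ["case"] * 10 + ["control"] * 10, n_perm=100, seed=0)
        t = de.table.sort_values("rp_up")
        assert np.all(np.diff(t["pfp_up"].to_numpy()) >= -1e-12)
        t = de.table.sort_values("rp_down")
        assert np.all(np.diff(t["pfp_down"].to_numpy()) >= -1e-12)

    def test_seed_reproducible_and_nperm_stable(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(25, 1, size=(60, 16))
        Y[:5, :8] -= 1.2
        groups = ["case"] * 8 + ["control"] * 8
        a = rank_product_test(_expr(Y), groups, n_perm=300, seed=7)
        b = rank_product_test(_expr(Y), groups, n_perm=300, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = rank_product_test(_expr(Y), groups, n_perm=600, seed=7)
        # doubling permutations moves pfp by less than ~2 binomial SE
        diff = np.abs(a.table["pfp_up"] - c.table["pfp_up"])
        se = np.sqrt(a.table["pfp_up"] * (1 - a.table["pfp_up"]) / 300).clip(lower=1e-3)
        assert (diff < 2 * 60 * se + 0.05).all()

    def test_small_group_raises(self):
        Y = _expr(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="at least 2"):
            rank_product_test(Y, ["case", "control", "control", "control"], n_perm=50)

    def test_tiny_nperm_warns(self):
        Y = _expr(np.random.default_rng(0).normal(size=(5, 8)))
        with pytest.warns(UserWarning, match="n_perm"):
            rank_product_test(Y, ["case"] * 4 + ["control"] * 4, n_perm=5)


class TestFoldChange:
    def test_one_cycle_difference_doubles(self):
        Y = np.array([[24.0, 24.0, 25.0, 25.0]])
        fc = fold_change_ct(_expr(Y), ["case", "case", "control", "control"], case_label="case")
        assert fc.iloc[0] == pytest.approx(2.0)

    def test_equal_means_give_unit_fold_change(self):
        Y = np.array([[25.0, 26.0, 25.5, 25.5]])
        fc = fold_change_ct(_expr(Y), ["case", "case", "control", "control"], case_label="case")
        assert fc.iloc[0] == pytest.approx(1.0)

    def test_planted_effect_recovered_within_mc_error(self):
        target = 1.5
        effect = np.log2(target)
        fcs = []
        for seed in range(20):
            r = np.random.default_rng(400 + seed)
            Y = 25 + 0.3 * r.standard_normal((1, 40))
            Y[0, :20] -= effect
            fcs.append(
                fold_change_ct(_expr(Y), GROUPS_20V20, case_label="case").iloc[0]
            )
        se = np.std(fcs, ddof=1) / np.sqrt(len(fcs))
        assert abs(np.mean(fcs) - target) < 3 * se


class TestSignificantFeatures:
    def test_all_pfp_one_gives_empty_signature(self):
        rng = np.random.default_rng(13)
        de = rank_product_test(
            _expr(rng.normal(25, 1, (10, 8))), ["case"] * 4 + ["control"] * 4, n_perm=100, seed=0
        )
        de.table["pfp_up"] = 1.0
        de.table["pfp_down"] = 1.0
        assert len(significant_features(de)) == 0

    def test_each_feature_appears_once(self):
        rng = np.random.default_rng(14)
        Y = rng.normal(25, 0.5, (30, 20))
        Y[:5, :10] -= 2
        de = rank_product_test(_expr(Y), ["case"] * 10 + ["control"] * 10, n_perm=200, seed=0)
        sig = significant_features(de)
        assert sig["mirna"].is_unique


class TestIntersect:
    def _sig(self, names, direction="up"):
        return pd.DataFrame(
            {
                "mirna": names,
                "direction": [direction] * len(names),
                "fold_change": [1.5] * len(names),
                "fdr": np.linspace(0.001, 0.04, len(names)),
            }
        )

    def test_disjoint_signatures_empty(self):
        out = intersect_signatures(self._sig(["miR-1", "miR-2"]), self._sig(["miR-3"]))
        assert len(out) == 0

    def test_identical_signatures_identity(self):
        a = self._sig(["miR-1", "miR-2", "miR-3"])
        out = intersect_signatures(a, a.copy())
        assert list(out["mirna"]) == ["miR-1", "miR-2", "miR-3"]

    def test_name_styles_match_after_normalization(self):
        a = self._sig(["hsa-miR-885-5p"])
        b = self._sig(["miR-885-5P"], direction="down")
        out = intersect_signatures(a, b)
        assert len(out) == 1
        assert out["direction_a"].iloc[0] == "up" and out["direction_b"].iloc[0] == "down"

    def test_ordered_by_first_signature_fdr(self):
        a = self._sig(["miR-2", "miR-1"])
        b = self._sig(["miR-1", "miR-2"])
        out = intersect_signatures(a, b)
        assert list(out["mirna"]) == ["miR-2", "miR-1"]


def test_bh_adjustment_monotone_and_above_p():
    rng = np.random.default_rng(15)
    p = rng.uniform(size=40)
    adj = _bh(p)
    assert np.all(adj >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
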