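import dendropy
import numpy as np
import pytest

from anna.phylo import (
    align_traits,
    ancestral_states,
    blomberg_k,
    bm_covariance,
    fit_bm,
    fit_pagel_lambda,
    lambda_transform,
    normalize_taxon,
    phenogram_export,
    read_newick,
)
from anna.synthetic import generate_yule_tree, simulate_bm


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestBMCovariance:
    def test_two_tips_no_shared_path(self):
        labels, cov = bm_covariance(newick("(A:1,B:1);"))
        assert labels == ["A", "B"]
        np.testing.assert_allclose(cov, np.eye(2))

    def test_three_tip_path_sums(self):
        labels, cov = bm_covariance(newick("((A:1,B:1):1,C:2);"))
        idx = {t: i for i, t in enumerate(labels)}
        assert cov[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert cov[idx["A"], idx["C"]] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(cov), 2.0)

    def test_matches_per_pair_mrca_oracle(self):
        tree = generate_yule_tree(24, 1.0, seed=5)
        labels, cov = bm_covariance(tree)
        # oracle: explicit MRCA depth per tip pair via dendropy
        pdm = {}
        tree2 = tree.clone(depth=1)
        tree2.is_rooted = True
        tree2.encode_bipartitions()
        depths = {}
        for node in tree2.preorder_node_iter():
            depths[node] = (
                0.0 if node.parent_node is None
                else depths[node.parent_node] + node.edge.length
            )
        taxa = {t.label: t for t in tree2.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    mrca = tree2.mrca(taxa=[taxa[a], taxa[b]])
                    assert cov[i, j] == pytest.approx(depths[mrca]), (a, b)

    def test_ultrametric_diagonal_constant(self):
        tree = generate_yule_tree(12, 1.0, seed=9)
        _, cov = bm_covariance(tree)
        np.testing.assert_allclose(np.diag(cov), np.diag(cov)[0])


class TestLambdaTransform:
    def test_lambda_zero_is_diagonal(self):
        _, cov = bm_covariance(generate_yule_tree(8, 1.0, seed=2))
        np.testing.assert_allclose(lambda_transform(cov, 0.0), np.diag(np.diag(cov)))

    def test_lambda_one_is_identity_transform(self):
        _, cov = bm_covariance(generate_yule_tree(8, 1.0, seed=2))
        np.testing.assert_allclose(lambda_transform(cov, 1.0), cov)


class TestFitBM:
    def test_star_tree_reduces_to_iid(self):
        v = 2.5
        n = 12
        rng = np.random.default_rng(1)
        x = rng.normal(3.0, 1.0, n)
        fit = fit_bm(x, v * np.eye(n))
        assert fit.mu == pytest.approx(x.mean())
        assert fit.sigma2 == pytest.approx(x.var() / v)

    @pytest.mark.parametrize("seed", range(5))
    def test_ml_optimum_beats_perturbations(self, seed):
        rng = np.random.default_rng(seed)
        tree = generate_yule_tree(10, 1.0, seed=seed)
        labels, cov = bm_covariance(tree)
        x = align_traits(simulate_bm(tree, 1.0, seed=seed + 50), tree)
        fit = fit_bm(x, cov)

        def loglik(mu, s2):
            n = len(x)
            r = x - mu
            ci = np.linalg.solve(cov, r)
            _, logdet = np.linalg.slogdet(cov)
            return -0.5 * (
                n * np.log(2 * np.pi * s2) + logdet + r @ ci / s2
            )

        assert fit.loglik == pytest.approx(loglik(fit.mu, fit.sigma2))
        for dmu in (-0.3, 0.3):
            for f in (0.7, 1.4):
                assert fit.loglik >= loglik(fit.mu + dmu, fit.sigma2 * f)

    def test_rate_recovery_under_bm(self):
        tree = generate_yule_tree(128, 1.0, seed=21)
        _, cov = bm_covariance(tree)
        est = [
            fit_bm(align_traits(simulate_bm(tree, 1.0, seed=s), tree), cov).sigma2
            for s in range(60)
        ]
        assert 0.9 <= np.mean(est) <= 1.1

    def test_constant_trait_flagged_degenerate(self):
        fit = fit_bm(np.full(5, 2.0), np.eye(5))
        assert fit.degenerate
        assert fit.sigma2 == 0.0


class TestPagelLambda:
    def test_frozen_phytools_oracle_strong_signal(self):
        """Fixture computed once with an independent reference
        implementation (phytools::phylosig): lambda-hat just above 1,
        logL0 = -32.92404595."""
        tree = generate_yule_tree(16, 1.0, seed=7)
        x = simulate_bm(tree, sigma2=1.0, root=5.0, seed=11)
        res = fit_pagel_lambda(x, tree)
        assert res.estimate == pytest.approx(1.0)  # capped at 1 by default
        assert res.null_loglik == pytest.approx(-32.92404595, abs=1e-6)
        res_free = fit_pagel_lambda(x, tree, allow_above_one=True)
        assert res_free.estimate == pytest.approx(1.00940799, abs=2e-3)
        assert res_free.alt_loglik == pytest.approx(-20.43016474, abs=2e-3)

    def test_frozen_phytools_oracle_no_signal(self):
        tree = generate_yule_tree(16, 1.0, seed=7)
        x = simulate_bm(tree, sigma2=1.0, root=5.0, lam=0.5, seed=13)
        res = fit_pagel_lambda(x, tree)
        assert res.estimate == pytest.approx(0.0, abs=1e-3)
        assert res.null_loglik == pytest.approx(-28.57445470, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_recovery_bm_vs_iid_small(self):
        tree = generate_yule_tree(64, 1.0, seed=3)
        labels, _ = bm_covariance(tree)
        rng = np.random.default_rng(0)
        bm = [
            fit_pagel_lambda(simulate_bm(tree, 1.0, seed=100 + i), tree).estimate
            for i in range(15)
        ]
        iid = [
            fit_pagel_lambda(
                dict(zip(labels, rng.standard_normal(64))), tree
            ).estimate
            for i in range(15)
        ]
        assert np.mean(bm) >= 0.9
        assert np.mean(iid) <= 0.1

    def test_boundary_mixture_halves_p(self):
        tree = generate_yule_tree(32, 1.0, seed=4)
        x = simulate_bm(tree, 1.0, seed=8)
        plain = fit_pagel_lambda(x, tree)
        mixed = fit_pagel_lambda(x, tree, boundary_mixture=True)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)

    def test_constant_trait_rejected(self):
        tree = generate_yule_tree(8, 1.0, seed=1)
        labels, _ = bm_covariance(tree)
        with pytest.raises(ValueError, match="constant"):
            fit_pagel_lambda(dict.fromkeys(labels, 1.0), tree)


class TestBlombergK:
    def test_frozen_phytools_oracle(self):
        """K statistic equals the reference value to 8 decimals."""
        tree = generate_yule_tree(16, 1.0, seed=7)
        x = simulate_bm(tree, sigma2=1.0, root=5.0, seed=11)
        res = blomberg_k(x, tree, n_perm=500, seed=1)
        assert res.estimate == pytest.approx(2.46745109, abs=1e-7)
        assert res.p_value <= 0.01

    def test_affine_invariance(self):
        tree = generate_yule_tree(20, 1.0, seed=6)
        x = simulate_bm(tree, 1.0, seed=10)
        k1 = blomberg_k(x, tree, n_perm=200, seed=2).estimate
        k2 = blomberg_k(
            {t: 3.0 * v - 7.0 for t, v in x.items()}, tree, n_perm=200, seed=2
        ).estimate
        assert k1 == pytest.approx(k2)

    def test_p_floor_counts_observed_arrangement(self):
        tree = generate_yule_tree(16, 1.0, seed=7)
        x = simulate_bm(tree, 1.0, seed=11)
        res = blomberg_k(x, tree, n_perm=400, seed=3)
        assert res.p_value >= 1.0 / 401

    def test_seed_is_required(self):
        tree = generate_yule_tree(8, 1.0, seed=1)
        x = simulate_bm(tree, 1.0, seed=2)
        with pytest.raises(ValueError, match="seed"):
            blomberg_k(x, tree, n_perm=100)

    def test_mean_near_one_under_bm_small(self):
        tree = generate_yule_tree(64, 1.0, seed=3)
        ks = [
            blomberg_k(
                simulate_bm(tree, 1.0, seed=200 + i), tree, n_perm=50, seed=i
            ).estimate
            for i in range(30)
        ]
        assert 0.8 <= np.mean(ks) <= 1.2


class TestAncestralStates:
    def test_two_tip_root_is_inverse_variance_weighted_mean(self):
        anc = ancestral_states({"A": 0.0, "B": 2.0}, newick("(A:1,B:3);"))
        root = [n for n in anc.nodes if n.parent is None][0]
        assert root.estimate == pytest.approx((0 / 1 + 2 / 3) / (1 / 1 + 1 / 3))

    def test_equal_branches_symmetric(self):
        anc = ancestral_states({"A": 0.0, "B": 2.0}, newick("(A:1,B:1);"))
        root = [n for n in anc.nodes if n.parent is None][0]
        assert root.estimate == pytest.approx(1.0)
        assert root.ci_high - root.estimate == pytest.approx(
            root.estimate - root.ci_low
        )

    def test_ci_brackets_estimate_everywhere(self):
        tree = generate_yule_tree(20, 1.0, seed=12)
        anc = ancestral_states(simulate_bm(tree, 1.0, seed=13), tree)
        for n in anc.nodes:
            assert n.ci_low <= n.estimate <= n.ci_high

    @pytest.mark.parametrize("seed", range(10))
    def test_internal_estimates_within_tip_range(self, seed):
        tree = generate_yule_tree(15, 1.0, seed=seed)
        x = simulate_bm(tree, 1.0, seed=seed + 77)
        anc = ancestral_states(x, tree)
        lo, hi = min(x.values()), max(x.values())
        for n in anc.internal():
            assert lo - 1e-9 <= n.estimate <= hi + 1e-9

    def test_zero_rate_returns_constant_truth(self):
        tree = generate_yule_tree(10, 1.0, seed=14)
        labels, _ = bm_covariance(tree)
        x = {t: 4.2 + 1e-9 * i for i, t in enumerate(labels)}  # numerically constant
        anc = ancestral_states(x, tree)
        for n in anc.internal():
            assert n.estimate == pytest.approx(4.2, abs=1e-6)
            assert n.ci_high - n.ci_low == pytest.approx(0.0, abs=1e-6)


class TestPhenogram:
    def test_segment_count_and_tip_coordinates(self, tmp_path):
        tree = generate_yule_tree(8, 1.0, seed=15)
        x = simulate_bm(tree, 1.0, seed=16)
        anc = ancestral_states(x, tree, trait="H")
        out = tmp_path / "seg.csv"
        phenogram_export(anc, out, figure_path=tmp_path / "fig.png")
        import pandas as pd

        seg = pd.read_csv(out)
        assert len(seg) == len(anc.nodes) - 1  # one segment per non-root node
        depths = {n.id: n.time for n in anc.nodes}
        for _, row in seg.iterrows():
            if row["node"] in x:  # tip rows end at the observed value
                assert row["y1"] == pytest.approx(x[row["node"]])
                assert row["t1"] == pytest.approx(depths[row["node"]])
        q = pd.read_csv(tmp_path / "seg_quartiles.csv")
        assert list(q["stat"]) == ["min", "q1", "median", "q3", "max"]
        assert (tmp_path / "fig.png").exists()

    def test_two_tip_segments_share_root_point(self, tmp_path):
        anc = ancestral_states({"A": 0.0, "B": 2.0}, newick("(A:1,B:1);"))
        out = tmp_path / "seg.csv"
        phenogram_export(anc, out)
        import pandas as pd

        seg = pd.read_csv(out)
        assert len(seg) == 2
        assert seg["y0"].nunique() == 1 and seg["t0"].nunique() == 1


class TestNameNormalization:
    def test_case_and_underscores(self):
        assert normalize_taxon("Pan_troglodytes ") == "pan troglodytes"

    def test_align_with_genus_fallback_warns(self):
        tree = newick("(Homo_sapiens:1,Pan_troglodytes:1);")
        with pytest.warns(UserWarning, match="genus"):
            x = align_traits({"homo sp.": 1.0, "pan TROGLODYTES": 2.0}, tree)
        np.testing.assert_allclose(x, [1.0, 2.0])

    def test_unmatched_tip_raises(self):
        tree = newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            align_traits({"A": 1.0}, tree)


class TestNewickIO:
    def test_missing_branch_length_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B);\n")
        with pytest.raises(ValueError, match="length"):
            read_newick(p)

    def test_round_trip(self, tmp_path):
        from anna.phylo import write_newick

        tree = generate_yule_tree(9, 1.0, seed=17)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        l1, c1 = bm_covariance(tree)
        l2, c2 = bm_covariance(back)
        assert l1 == l2
        np.testing.assert_allclose(c1, c2, atol=1e-9)
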