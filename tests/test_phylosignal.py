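"""Phylogenetic covariance, Pagel's lambda ML fit and uncertainty propagation."""

import numpy as np
import pandas as pd
import pytest

from canopyresponse import (Phylogeny, SyntheticConfig, clade_subset_signal,
                            fit_lambda, lambda_transform,
                            lambda_with_uncertainty, simulate_tree_and_traits,
                            vcv_matrix)
from canopyresponse.phylosignal import profile_loglik


def brute_force_vcv(phylo):
    """Independent oracle: shared branch length from per-tip ancestor edge sets."""
    tree = phylo.tree
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = dict(edges)
    labels = list(paths)
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(paths[a]) & set(paths[b])
            V[i, j] = sum(paths[a][e] for e in shared)
    return labels, V


class TestVcv:
    def test_two_tip_star(self):
        phylo = Phylogeny.from_newick("(A:1,B:1);", is_path=False)
        labels, V = vcv_matrix(phylo)
        ref = pd.DataFrame(V, index=labels, columns=labels)
        assert ref.loc["A", "A"] == 1 and ref.loc["B", "B"] == 1
        assert ref.loc["A", "B"] == 0

    def test_three_tip_hand_computation(self, small_tree):
        labels, V = vcv_matrix(small_tree)
        ref = pd.DataFrame(V, index=labels, columns=labels)
        assert ref.loc["A", "A"] == 2 and ref.loc["B", "B"] == 2
        assert ref.loc["A", "B"] == 1
        assert ref.loc["A", "D"] == 0 and ref.loc["D", "D"] == 2

    def test_random_tree_matches_brute_force(self):
        cfg = SyntheticConfig(n_species=20, seed=4)
        phylo, _ = simulate_tree_and_traits(cfg)
        labels, V = vcv_matrix(phylo)
        blabels, BV = brute_force_vcv(phylo)
        order = [blabels.index(l) for l in labels]
        assert np.allclose(V, BV[np.ix_(order, order)], atol=1e-9)

    def test_unknown_tip_rejected(self, small_tree):
        with pytest.raises(KeyError):
            vcv_matrix(small_tree, tip_subset=["A", "Z"])

    def test_subset_equals_submatrix_of_full(self):
        """Pruning preserves root-to-MRCA depths, so the clade VCV is a submatrix."""
        cfg = SyntheticConfig(n_species=16, seed=8)
        phylo, _ = simulate_tree_and_traits(cfg)
        labels, V = vcv_matrix(phylo)
        subset = labels[::2]
        sub_labels, SV = vcv_matrix(phylo, tip_subset=subset)
        idx = [labels.index(l) for l in sub_labels]
        assert np.allclose(SV, V[np.ix_(idx, idx)], atol=1e-9)


class TestLambdaTransform:
    def test_endpoints_and_half(self, small_tree):
        _, V = vcv_matrix(small_tree)
        assert np.allclose(lambda_transform(V, 1.0), V)
        assert np.allclose(lambda_transform(V, 0.0), np.diag(np.diag(V)))
        half = lambda_transform(V, 0.5)
        assert np.allclose(np.diag(half), np.diag(V))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(half[off], 0.5 * V[off])

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_out_of_range_rejected(self, lam):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(3), lam)


class TestFitLambda:
    def _bm_trait(self, seed, n=40, noise=0.0):
        cfg = SyntheticConfig(n_species=n, seed=seed)
        phylo, _ = simulate_tree_and_traits(cfg)
        labels, V = vcv_matrix(phylo)
        rng = np.random.default_rng(seed + 500)
        y = np.linalg.cholesky(V) @ rng.standard_normal(n)
        if noise:
            y = y + noise * np.sqrt(np.diag(V).mean()) * rng.standard_normal(n)
        return phylo, pd.Series(y, index=labels), V, labels

    def test_matches_dense_grid_search(self):
        """lambda-hat agrees with a 2001-point profiled-likelihood grid."""
        phylo, y, V, labels = self._bm_trait(2, noise=0.5)
        res = fit_lambda(y, phylo)
        grid = np.linspace(0, 1, 2001)
        ll = [profile_loglik(y.reindex(labels).to_numpy(), V, g) for g in grid]
        assert abs(res.lambda_hat - grid[int(np.argmax(ll))]) <= 1e-3
        assert res.loglik >= max(ll) - 1e-8

    def test_matches_reference_implementation(self):
        """Frozen oracle values computed with phytools::phylosig (R) on the
        identical deterministic dataset."""
        cfg = SyntheticConfig(n_species=40, seed=7)
        phylo, _ = simulate_tree_and_traits(cfg)
        labels, V = vcv_matrix(phylo)
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(5)
        y = (L @ rng.standard_normal(len(labels))
             + 0.8 * rng.standard_normal(len(labels)) * np.sqrt(np.diag(V).mean()))
        res = fit_lambda(pd.Series(y, index=labels), phylo)
        assert res.lambda_hat == pytest.approx(0.7672773, abs=1e-4)
        assert res.loglik == pytest.approx(-135.7183, abs=1e-3)
        assert res.loglik0 == pytest.approx(-149.3644, abs=1e-3)
        assert res.p_value == pytest.approx(1.749134e-07, rel=1e-3)

    def test_affine_invariance(self):
        phylo, y, _, _ = self._bm_trait(3, noise=0.3)
        a = fit_lambda(y, phylo)
        b = fit_lambda(3.7 * y - 11.0, phylo)
        assert abs(a.lambda_hat - b.lambda_hat) < 1e-6

    def test_lrt_nonnegative_and_p_valid(self):
        for seed in range(5):
            phylo, y, _, _ = self._bm_trait(10 + seed, noise=1.0)
            res = fit_lambda(y, phylo)
            assert res.lrt_stat >= 0
            assert 0.0 <= res.p_value <= 1.0

    def test_bm_recovery_and_permutation_contrast(self):
        lams_bm, lams_perm = [], []
        rng = np.random.default_rng(77)
        for seed in range(15):
            phylo, y, _, _ = self._bm_trait(100 + seed, n=48)
            lams_bm.append(fit_lambda(y, phylo).lambda_hat)
            shuffled = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            lams_perm.append(fit_lambda(shuffled, phylo).lambda_hat)
        assert np.median(lams_bm) >= 0.8
        assert np.median(lams_perm) <= 0.2

    def test_degenerate_inputs_rejected(self, small_tree):
        with pytest.raises(ValueError, match="constant"):
            fit_lambda(pd.Series({"A": 1.0, "B": 1.0, "D": 1.0}), small_tree)
        with pytest.raises(ValueError, match="3 tips"):
            fit_lambda(pd.Series({"A": 1.0, "B": 2.0}), small_tree)


class TestUncertaintyPropagation:
    def _omega_table(self, labels, centres, width):
        return pd.DataFrame(
            {"species": labels,
             "ci_low": centres - width / 2,
             "ci_high": centres + width / 2}
        )

    def test_zero_width_cis_reduce_to_single_fit(self):
        cfg = SyntheticConfig(n_species=24, seed=14)
        phylo, truth = simulate_tree_and_traits(cfg)
        centres = truth.params.set_index("species")["trait"]
        tab = self._omega_table(list(centres.index), centres.to_numpy(), 0.0)
        res = lambda_with_uncertainty(tab, phylo, n_iter=5, seed=3)
        single = fit_lambda(centres, phylo)
        assert res.median_lambda == pytest.approx(single.lambda_hat, abs=1e-8)
        assert res.median_p == pytest.approx(single.p_value, rel=1e-6)
        assert len(res.iterations) == 5

    def test_single_iteration_runs(self):
        cfg = SyntheticConfig(n_species=12, seed=15)
        phylo, truth = simulate_tree_and_traits(cfg)
        centres = truth.params.set_index("species")["trait"]
        tab = self._omega_table(list(centres.index), centres.to_numpy(), 0.5)
        res = lambda_with_uncertainty(tab, phylo, n_iter=1, seed=0)
        assert res.n_iter == 1 and len(res.iterations) == 1

    def test_wide_cis_attenuate_signal(self):
        meds = {}
        for width in (0.01, 2.0):
            vals = []
            for seed in (31, 32, 33, 34, 35):
                cfg = SyntheticConfig(n_species=32, seed=seed)
                phylo, truth = simulate_tree_and_traits(cfg)
                centres = truth.params.set_index("species")["trait"]
                scale = centres.std() or 1.0
                tab = self._omega_table(list(centres.index),
                                        centres.to_numpy() / scale, width)
                res = lambda_with_uncertainty(tab, phylo, n_iter=20, seed=seed)
                vals.append(res.median_lambda)
            meds[width] = np.median(vals)
        assert meds[0.01] >= meds[2.0]

    def test_species_without_finite_ci_are_pruned(self):
        cfg = SyntheticConfig(n_species=12, seed=16)
        phylo, truth = simulate_tree_and_traits(cfg)
        centres = truth.params.set_index("species")["trait"]
        tab = self._omega_table(list(centres.index), centres.to_numpy(), 0.1)
        tab.loc[0, "ci_low"] = np.nan
        res = lambda_with_uncertainty(tab, phylo, n_iter=2, seed=0)
        assert res.n_tips == 11


class TestCladeSubsets:
    def test_single_clade_equals_full_run(self):
        cfg = SyntheticConfig(n_species=16, seed=20)
        phylo, truth = simulate_tree_and_traits(cfg)
        centres = truth.params.set_index("species")["trait"]
        tab = pd.DataFrame({"species": centres.index,
                            "ci_low": centres - 0.05, "ci_high": centres + 0.05})
        labels = {s: "everything" for s in centres.index}
        out = clade_subset_signal(tab, phylo, labels, n_iter=4, seed=9)
        assert out["everything"].median_lambda == pytest.approx(
            out["all"].median_lambda, abs=1e-9)

    def test_too_small_clade_reported_not_fatal(self):
        cfg = SyntheticConfig(n_species=10, seed=21)
        phylo, truth = simulate_tree_and_traits(cfg)
        centres = truth.params.set_index("species")["trait"]
        tab = pd.DataFrame({"species": centres.index,
                            "ci_low": centres - 0.05, "ci_high": centres + 0.05})
        labels = {s: ("tiny" if i < 2 else "rest")
                  for i, s in enumerate(centres.index)}
        out = clade_subset_signal(tab, phylo, labels, n_iter=2, seed=0)
        assert out["tiny"] is None
        assert out["rest"] is not None and out["all"] is not None

    def test_signal_confined_to_one_clade(self):
        """BM within clade A, iid in clade B: the contrast shows up per clade."""
        la, lb = [], []
        for seed in (41, 42, 43, 44, 45):
            cfg = SyntheticConfig(n_species=40, seed=seed)
            phylo, truth = simulate_tree_and_traits(cfg)
            clades = phylo.clades
            a_tips = [s for s, c in clades.items() if c == "cladeA"]
            b_tips = [s for s, c in clades.items() if c == "cladeB"]
            if len(a_tips) < 8 or len(b_tips) < 8:
                continue
            labels, V = vcv_matrix(phylo)
            rng = np.random.default_rng(seed)
            y = pd.Series(np.linalg.cholesky(V) @ rng.standard_normal(len(labels)),
                          index=labels)
            y.loc[b_tips] = rng.standard_normal(len(b_tips)) * y.std()
            tab = pd.DataFrame({"species": labels, "ci_low": y.reindex(labels),
                                "ci_high": y.reindex(labels)})
            out = clade_subset_signal(tab, phylo, clades, n_iter=1, seed=seed)
            la.append(out["cladeA"].median_lambda)
            lb.append(out["cladeB"].median_lambda)
        assert np.median(la) > np.median(lb)
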