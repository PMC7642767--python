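"""Phylogenetic covariance, Pagel's lambda and Blomberg's K."""

import math
import subprocess
import sys

import numpy as np
import pytest

from cvalkit import comparative, synth
from cvalkit.comparative import _profile, lambda_transform
from cvalkit.errors import (
    EstimationError,
    LambdaUnidentifiableError,
    ValidationError,
)


def star_tree(n, lengths=None):
    lengths = lengths or [1.0] * n
    tips = ",".join(f"T{i}:{lengths[i]}" for i in range(n))
    return comparative.load_tree(f"({tips});")


class TestVcv:
    def test_root_cherry(self):
        C, labels = comparative.vcv("(A:1,B:1);")
        assert labels == ["A", "B"]
        assert np.allclose(C, np.eye(2))

    def test_three_tip_path_lengths(self):
        C, labels = comparative.vcv("((A:1,B:1):1,C:2);")
        idx = {lab: i for i, lab in enumerate(labels)}
        assert C[idx["A"], idx["A"]] == pytest.approx(2)
        assert C[idx["A"], idx["B"]] == pytest.approx(1)
        assert C[idx["C"], idx["C"]] == pytest.approx(2)
        assert C[idx["A"], idx["C"]] == 0

    def test_yule_vcv_symmetric_psd(self, yule16):
        C, _ = comparative.vcv(yule16)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-9

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            comparative.vcv("((A:1,A:1):1,B:2);")

    def test_rescaling_tree_rescales_c(self, yule16):
        C, labels = comparative.vcv(yule16)
        scaled = comparative.load_tree(yule16.as_string(schema="newick"))
        for edge in scaled.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 3.5
        C2, labels2 = comparative.vcv(scaled)
        order = [labels2.index(l) for l in labels]
        assert np.allclose(C2[np.ix_(order, order)], 3.5 * C, rtol=1e-9)


class TestBmLoglik:
    def test_standard_normal_at_mean(self):
        ll = comparative.bm_loglik(np.array([0.0]), np.eye(1), 1.0, 0.0)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_matches_dense_formula_oracle(self, rng):
        C = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        x = rng.normal(size=3)
        sigma2, root = 1.7, 0.3
        cov = sigma2 * C
        resid = x - root
        oracle = (-0.5 * (3 * math.log(2 * math.pi)
                          + math.log(np.linalg.det(cov))
                          + resid @ np.linalg.inv(cov) @ resid))
        assert comparative.bm_loglik(x, C, sigma2, root) == pytest.approx(
            oracle, abs=1e-9)

    def test_scale_identifiability_identity(self, rng):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        x = rng.normal(size=2)
        a = comparative.bm_loglik(x, C, 1.3, 0.1)
        b = comparative.bm_loglik(x, 4.0 * C, 1.3 / 4.0, 0.1)
        assert a == pytest.approx(b, abs=1e-9)


class TestFitLambda:
    def test_grid_search_oracle(self, interior_lambda_dataset):
        tree, traits = interior_lambda_dataset
        fit = comparative.fit_lambda(tree, traits)
        C, labels = comparative.vcv(tree)
        x = comparative.align_trait(traits, labels)
        grid = np.linspace(0.0, 1.0, 2001)
        logls = [_profile(x, lambda_transform(C, lam))[0] for lam in grid]
        assert 0.0 < fit.lambda_hat < 1.0
        assert abs(fit.lambda_hat - grid[int(np.argmax(logls))]) < 1e-3
        assert fit.logl_max >= max(fit.logl_lambda0, fit.logl_lambda1) - 1e-9

    def test_recovers_full_signal(self):
        lams = []
        for s in range(20):
            tree = synth.simulate_yule_tree(
                synth.TreeSimConfig(n_tips=64, seed=500 + s))
            traits = synth.simulate_bm_trait(
                tree, synth.BmParams(sigma2=1.0, lambda_true=1.0, seed=600 + s))
            lams.append(comparative.fit_lambda(tree, traits).lambda_hat)
        assert np.mean(lams) >= 0.90

    def test_recovers_absent_signal(self):
        lams = []
        for s in range(20):
            tree = synth.simulate_yule_tree(
                synth.TreeSimConfig(n_tips=64, seed=700 + s))
            traits = synth.simulate_bm_trait(
                tree, synth.BmParams(sigma2=1.0, lambda_true=0.0, seed=800 + s))
            lams.append(comparative.fit_lambda(tree, traits).lambda_hat)
        assert np.mean(lams) <= 0.10

    def test_star_tree_unidentifiable(self):
        traits = {f"T{i}": float(i) for i in range(6)}
        with pytest.raises(LambdaUnidentifiableError):
            comparative.fit_lambda(star_tree(6), traits)

    def test_invariant_to_branch_rescaling(self, interior_lambda_dataset):
        tree, traits = interior_lambda_dataset
        fit = comparative.fit_lambda(tree, traits)
        scaled = comparative.load_tree(tree.as_string(schema="newick"))
        for edge in scaled.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 10.0
        fit2 = comparative.fit_lambda(scaled, traits)
        assert fit2.lambda_hat == pytest.approx(fit.lambda_hat, abs=1e-4)


class TestBlombergK:
    def test_unit_star_tree_gives_exactly_one(self):
        traits = {f"T{i}": v for i, v in enumerate([1.0, 3.0, 2.5, -1.0, 0.3])}
        k = comparative.blomberg_k(star_tree(5), traits)
        assert k == pytest.approx(1.0, abs=1e-12)

    def test_brownian_traits_average_near_one(self):
        ks = []
        for s in range(60):
            tree = synth.simulate_yule_tree(
                synth.TreeSimConfig(n_tips=64, seed=900 + s))
            traits = synth.simulate_bm_trait(
                tree, synth.BmParams(sigma2=1.0, lambda_true=1.0, seed=950 + s))
            ks.append(comparative.blomberg_k(tree, traits))
        ks = np.array(ks)
        se = ks.std(ddof=1) / math.sqrt(len(ks))
        assert abs(ks.mean() - 1.0) < 3 * se

    def test_white_noise_traits_give_low_k(self):
        rng = np.random.default_rng(3)
        ks = []
        for s in range(50):
            tree = synth.simulate_yule_tree(
                synth.TreeSimConfig(n_tips=64, seed=1100 + s))
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            traits = dict(zip(labels, rng.normal(size=len(labels))))
            ks.append(comparative.blomberg_k(tree, traits))
        assert np.median(ks) < 1.0

    def test_invariant_to_branch_rescaling(self, yule16):
        traits = synth.simulate_bm_trait(yule16, synth.BmParams(seed=77))
        k1 = comparative.blomberg_k(yule16, traits)
        scaled = comparative.load_tree(yule16.as_string(schema="newick"))
        for edge in scaled.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 0.25
        assert comparative.blomberg_k(scaled, traits) == pytest.approx(
            k1, rel=1e-9)


class TestPermutationTest:
    def test_structured_trait_significant(self):
        tree = synth.simulate_yule_tree(synth.TreeSimConfig(n_tips=32, seed=41))
        traits = synth.simulate_bm_trait(
            tree, synth.BmParams(sigma2=1.0, lambda_true=1.0, seed=42))
        res = comparative.k_permutation_p(tree, traits, n_perm=999, seed=7)
        assert res.p_perm <= 0.05
        assert res.p_perm >= 1 / 1000  # add-one boundary

    def test_deterministic_given_seed(self, yule16):
        traits = synth.simulate_bm_trait(yule16, synth.BmParams(seed=5))
        a = comparative.k_permutation_p(yule16, traits, n_perm=199, seed=11)
        b = comparative.k_permutation_p(yule16, traits, n_perm=199, seed=11)
        assert a.p_perm == b.p_perm

    def test_constant_trait_rejected(self, yule16):
        labels = [l.taxon.label for l in yule16.leaf_node_iter()]
        with pytest.raises(EstimationError, match="constant"):
            comparative.k_permutation_p(yule16, {l: 1.0 for l in labels})

    def test_null_p_values_uniform_on_unequal_star_tree(self):
        # exchangeable traits on a star tree with unequal tip lengths:
        # permutation p-values must be uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(55)
        lengths = list(rng.uniform(0.5, 3.0, size=8))
        tree_src = "(" + ",".join(f"T{i}:{lengths[i]}" for i in range(8)) + ");"
        ps = []
        for r in range(300):
            tree = comparative.load_tree(tree_src)
            traits = {f"T{i}": float(v) for i, v in
                      enumerate(rng.normal(size=8))}
            ps.append(comparative.k_permutation_p(
                tree, traits, n_perm=199, seed=r).p_perm)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestExternalOracle:
    def test_lambda_and_k_match_r_phytools(self, interior_lambda_dataset,
                                           tmp_path):
        """Independent cross-check against phytools::phylosig."""
        tree, traits = interior_lambda_dataset
        tree_path = tmp_path / "tree.nwk"
        trait_path = tmp_path / "traits.csv"
        tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
        synth.write_trait_csv(traits, trait_path)
        script = (
            'suppressMessages(library(phytools));'
            f'tree<-read.tree("{tree_path}");'
            f'tr<-read.csv("{trait_path}");'
            'x<-setNames(tr$value,tr$species);'
            'l<-phylosig(tree,x,method="lambda");'
            'k<-phylosig(tree,x,method="K");'
            'cat(sprintf("%.10f %.6f %.10f", l$lambda, l$logL, k))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r_lambda, r_logl, r_k = map(float, out.stdout.split())
        fit = comparative.fit_lambda(tree, traits)
        assert fit.lambda_hat == pytest.approx(r_lambda, abs=1e-3)
        assert fit.logl_max == pytest.approx(r_logl, abs=1e-3)
        assert comparative.blomberg_k(tree, traits) == pytest.approx(
            r_k, abs=1e-6)
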