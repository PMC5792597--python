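"""Independent contrasts, correlation structures, and PGLS."""

import math

import numpy as np
import pandas as pd
import pytest

import cetadiv as cd
from cetadiv.comparative import _LambdaWhitener
from cetadiv.errors import DomainError, TreeError, ValidationError
from cetadiv.simulate import TraitModel


class TestContrasts:
    def test_two_tip_closed_form(self, cherry_tree):
        cs = cd.compute_contrasts(cherry_tree, {"A": 4.0, "B": 2.0})
        assert cs.n_contrasts == 1
        assert abs(cs.contrasts[0][1]) == pytest.approx(math.sqrt(2))

    def test_constant_trait_gives_zero_contrasts(self, tree100):
        cs = cd.compute_contrasts(tree100, {t: 3.14 for t in tree100.tip_labels})
        assert np.allclose(cs.values, 0.0, atol=1e-12)
        assert cs.n_contrasts == tree100.n_tips - 1

    def test_three_tip_hand_recursion(self, three_tip_tree):
        # ((A:1,B:1):1,C:2) with x = (1, 3, 6):
        # contrast1 = (1-3)/sqrt(2); ancestor value 2, variance 1 + 0.5
        # contrast2 = (2-6)/sqrt(1.5 + 2)
        cs = cd.compute_contrasts(three_tip_tree, {"A": 1.0, "B": 3.0, "C": 6.0})
        vals = sorted(abs(v) for _, v in cs.contrasts)
        assert vals[0] == pytest.approx(2 / math.sqrt(2))
        assert vals[1] == pytest.approx(4 / math.sqrt(3.5))

    def test_polytomy_resolution_is_deterministic(self):
        t = cd.PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        trait = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 8.0}
        c1 = cd.compute_contrasts(t, trait).values
        c2 = cd.compute_contrasts(t, trait).values
        assert np.array_equal(c1, c2)
        assert len(c1) == 3

    def test_missing_tip_value_rejected(self, three_tip_tree):
        with pytest.raises(ValidationError, match="missing"):
            cd.compute_contrasts(three_tip_tree, {"A": 1.0, "B": 2.0})

    def test_zero_length_pair_needs_flag(self):
        t = cd.PhyloTree.from_newick("((A:0,B:0):1,C:2);")
        with pytest.raises(TreeError):
            cd.compute_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        cs = cd.compute_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0},
                                  allow_zero_length=True)
        assert np.all(np.isfinite(cs.values))

    def test_bm_contrast_variance_matches_sigma2(self):
        """Standardized BM contrasts have variance sigma^2 (here 2.5)."""
        tree = cd.simulate_yule_tree(120, 1.0, seed=5)
        model = TraitModel("bm", sigma2=2.5)
        samples = []
        for rep in range(150):
            trait = cd.simulate_trait(tree, model, seed=rep)
            samples.append(np.var(cd.compute_contrasts(tree, trait).values,
                                  ddof=1))
        assert np.mean(samples) == pytest.approx(2.5, rel=0.1)


class TestPicCorrelation:
    def test_perfect_linearity(self, tree100):
        trait = cd.simulate_trait(tree100, TraitModel("bm", sigma2=1.0), seed=1)
        y = {k: 2.0 * v for k, v in trait.items()}
        r, F, p = cd.pic_correlation(tree100, trait, y)
        assert r == pytest.approx(1.0)
        assert p <= 1e-12

    def test_sign_preserved_for_negative_association(self, tree100):
        trait = cd.simulate_trait(tree100, TraitModel("bm", sigma2=1.0), seed=2)
        y = {k: -v for k, v in trait.items()}
        r, _, _ = cd.pic_correlation(tree100, trait, y)
        assert r == pytest.approx(-1.0)

    def test_too_few_contrasts_rejected(self, cherry_tree):
        with pytest.raises(ValidationError):
            cd.pic_correlation(cherry_tree, {"A": 1, "B": 2}, {"A": 2, "B": 1})

    def test_matches_gls_matrix_oracle(self):
        """PIC r equals the GLS correlation under BM covariance.

        Oracle: project out the GLS mean with P = Vi - Vi 1 (1' Vi 1)^-1 1' Vi
        and correlate in the V^-1 inner product.
        """
        for seed in range(4):
            tree = cd.simulate_yule_tree(6, 1.0, seed=seed)
            x = cd.simulate_trait(tree, TraitModel("bm", sigma2=1.0),
                                  seed=100 + seed)
            y = cd.simulate_trait(tree, TraitModel("bm", sigma2=1.0),
                                  seed=200 + seed)
            labels, C = tree.shared_path_matrix()
            Vi = np.linalg.inv(C)
            one = np.ones(len(labels))
            P = Vi - Vi @ np.outer(one, one) @ Vi / (one @ Vi @ one)
            xv = np.array([x[l] for l in labels])
            yv = np.array([y[l] for l in labels])
            r_oracle = (xv @ P @ yv) / math.sqrt((xv @ P @ xv) * (yv @ P @ yv))
            r_pic, _, _ = cd.pic_correlation(tree, x, y)
            assert r_pic == pytest.approx(r_oracle, abs=1e-8)


class TestStructures:
    def test_ou_hand_entries(self):
        # cherry tips at patristic distance 0.4; outgroup at 2.0
        t = cd.PhyloTree.from_newick("((A:0.2,B:0.2):0.8,C:1.0);")
        labels, M = cd.ou_correlation(t, 1.0)
        i, j, k = (labels.index(x) for x in "ABC")
        assert M[i, i] == 1.0
        assert M[i, j] == pytest.approx(math.exp(-0.4))
        assert M[i, k] == pytest.approx(math.exp(-2.0))

    def test_ou_large_alpha_is_identity(self, three_tip_tree):
        _, M = cd.ou_correlation(three_tip_tree, 1e6)
        assert np.allclose(M, np.eye(3))

    def test_ou_positive_definite(self, tree100):
        _, M = cd.ou_correlation(tree100, 0.5)
        assert np.allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() > 0

    def test_lambda_one_is_bm(self, tree100):
        _, C = tree100.shared_path_matrix()
        _, V = cd.lambda_covariance(tree100, 1.0)
        assert np.allclose(V, C)

    def test_lambda_zero_is_diagonal(self, tree100):
        _, C = tree100.shared_path_matrix()
        _, V = cd.lambda_covariance(tree100, 0.0)
        assert np.allclose(V, np.diag(np.diag(C)))

    def test_lower_bound_negative_and_singular(self):
        tree = cd.simulate_yule_tree(10, 1.0, seed=8)
        lo, hi = cd.lambda_bounds(tree)
        assert lo < 0 < 1 < hi
        _, C = tree.shared_path_matrix()
        V = lo * C
        np.fill_diagonal(V, np.diag(C))
        assert abs(np.linalg.eigvalsh(V)[0]) < 1e-6 * np.max(np.diag(C))

    def test_out_of_interval_rejected(self, tree100):
        lo, hi = cd.lambda_bounds(tree100)
        with pytest.raises(DomainError, match="admissible"):
            cd.lambda_covariance(tree100, lo - 0.05)

    def test_lambda_whitener_matches_direct_cholesky(self, tree100):
        """The eigen-whitening shortcut reproduces the brute-force GLS RSS."""
        rng = np.random.default_rng(3)
        labels, C = tree100.shared_path_matrix()
        y = rng.normal(size=len(labels))
        X = np.column_stack([np.ones(len(labels)), rng.normal(size=len(labels))])
        lw = _LambdaWhitener(C, y, X)
        for lam in (0.0, 0.3, 0.9):
            ys, Xs, logdet = lw.whiten(lam)
            V = lam * C
            np.fill_diagonal(V, np.diag(C))
            L = np.linalg.cholesky(V)
            yd = np.linalg.solve(L, y)
            Xd = np.linalg.solve(L, X)
            assert logdet == pytest.approx(
                2 * np.sum(np.log(np.diag(L))), rel=1e-9)
            bs, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            bd, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
            assert np.allclose(bs, bd, atol=1e-8)


class TestPgls:
    def _dataset(self, tree, seed, beta=1.5):
        rng = np.random.default_rng(seed)
        x = cd.simulate_trait(tree, TraitModel("bm", sigma2=1.0), seed=seed)
        data = pd.DataFrame({"x": pd.Series(x)})
        noise = cd.simulate_trait(tree, TraitModel("bm", sigma2=0.25),
                                  seed=seed + 1)
        y = {s: 0.5 + beta * x[s] + noise[s] for s in tree.tip_labels}
        return y, data

    def test_identity_structure_equals_ols(self, tree100):
        y, data = self._dataset(tree100, 7)
        fit = cd.pgls_fit(tree100, y, data, ["x"], structure="identity")
        labels = sorted(tree100.tip_labels)
        X = np.column_stack([np.ones(len(labels)),
                             data.loc[labels, "x"].to_numpy()])
        yv = np.array([y[s] for s in labels])
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        assert fit.coefficients["Intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-10)

    def test_lambda_estimate_beats_endpoints(self, tree100):
        y, data = self._dataset(tree100, 9)
        fit = cd.pgls_fit(tree100, y, data, ["x"], structure="lambda")
        for fixed in (0.0, 1.0 - 1e-6):
            alt = cd.pgls_fit(tree100, y, data, ["x"], structure="lambda",
                              estimate_structure=False, structure_param=fixed)
            assert fit.log_likelihood >= alt.log_likelihood - 1e-8

    def test_ou_structure_recovers_slope(self, tree100):
        y, data = self._dataset(tree100, 11, beta=2.0)
        fit = cd.pgls_fit(tree100, y, data, ["x"], structure="ou")
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=0.3)
        assert fit.structure_param > 0

    def test_sequential_f_detects_signal_term(self, tree100):
        y, data = self._dataset(tree100, 13, beta=2.0)
        fit = cd.pgls_fit(tree100, y, data, ["x"], structure="lambda")
        assert fit.term_p["x"] < 1e-6
        assert fit.term_F["x"] > 30

    def test_categorical_terms_and_missing_cases(self, tree100):
        rng = np.random.default_rng(15)
        labels = tree100.tip_labels
        x = cd.simulate_trait(tree100, TraitModel("bm", sigma2=1.0), seed=15)
        group = {s: ("a" if rng.random() < 0.5 else "b") for s in labels}
        data = pd.DataFrame({"x": pd.Series(x),
                             "habitat": pd.Series(group)})
        data.loc[labels[:5], "x"] = np.nan  # incomplete cases dropped
        y = {s: x[s] + (1.0 if group[s] == "b" else 0.0)
             + rng.normal(0, 0.3) for s in labels}
        fit = cd.pgls_fit(tree100, y, data, ["x", "habitat"],
                          structure="lambda")
        assert fit.n == len(labels) - 5
        assert "habitat[b]" in fit.coefficients
        assert fit.term_p["habitat"] < 0.01

    def test_too_few_species_rejected(self, three_tip_tree):
        data = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
        with pytest.raises(ValidationError):
            # only two species carry the response: below terms + 2
            cd.pgls_fit(three_tip_tree, {"A": 1, "B": 2}, data,
                        ["x"], structure="identity")
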