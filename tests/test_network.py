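"""Network inference: evidence oracles, rank combination, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import rankdata

import monster as ms
from monster.io import GROUP_FINAL, GROUP_INITIAL
from monster.network import LOGISTIC_PENALTY, rank_normalize


def make_prior(M, tf_names, gene_names):
    return ms.MotifPrior(tf_ids=tuple(tf_names), gene_ids=tuple(gene_names),
                         M=np.asarray(M))


def partial_corr_oracle(x, y, conditioners):
    """Regress both vectors on [1, conditioners], correlate residuals, square."""
    n = len(x)
    design = np.column_stack([np.ones(n)] + list(conditioners))
    def resid(v):
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ coef
    rx, ry = resid(x), resid(y)
    return np.corrcoef(rx, ry)[0, 1] ** 2


class TestDirectEvidence:
    def test_identical_vectors_give_one(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(6)
        values = np.vstack([g, g])
        prior = make_prior([[1], [1]], ["TF1"], ["TF1", "G1"])
        d = ms.direct_evidence(values, prior)
        # TF vs its own row: perfect correlation, empty conditioning set
        assert d[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert d[1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_zero_mean_vectors_give_zero(self):
        tf = np.array([1.0, -1.0, 1.0, -1.0])
        gene = np.array([1.0, 1.0, -1.0, -1.0])
        values = np.vstack([tf, gene])
        prior = make_prior([[1], [1]], ["TF1"], ["TF1", "G1"])
        d = ms.direct_evidence(values, prior)
        assert d[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_residualization_oracle(self):
        """100 random (gene, TF) pairs with nonempty conditioning sets."""
        rng = np.random.default_rng(42)
        p, m, n = 25, 5, 12
        values = rng.standard_normal((p, n))
        gene_names = [f"TF{i}" for i in range(m)] + [f"G{j}" for j in range(p - m)]
        M = np.zeros((p, m), dtype=int)
        for j in range(m, p):
            M[j, rng.choice(m, size=2, replace=False)] = 1
        prior = make_prior(M, gene_names[:m], gene_names)
        d = ms.direct_evidence(values, prior)
        checked = 0
        while checked < 100:
            j = int(rng.integers(m, p))
            i = int(rng.integers(0, m))
            cond = [k for k in np.nonzero(M[j])[0] if k != i]
            expected = partial_corr_oracle(values[i], values[j],
                                           [values[k] for k in cond])
            assert d[j, i] == pytest.approx(expected, abs=1e-10)
            checked += 1

    def test_empty_prior_reduces_to_squared_pearson(self):
        rng = np.random.default_rng(7)
        p, m, n = 10, 3, 9
        values = rng.standard_normal((p, n))
        names = [f"TF{i}" for i in range(m)] + [f"G{j}" for j in range(p - m)]
        M = np.zeros((p, m), dtype=int)
        M[0, 0] = 1  # keep one motif so TFs survive; gene 0 is TF0 itself
        prior = make_prior(M, names[:m], names)
        d = ms.direct_evidence(values, prior)
        corr = np.corrcoef(values)
        for j in range(1, p):  # all genes with empty conditioning sets
            for i in range(m):
                assert d[j, i] == pytest.approx(corr[j, i] ** 2, abs=1e-10)

    def test_sample_permutation_invariance(self, small_dataset):
        expr, prior, _ = small_dataset
        values = expr.subset_values(GROUP_INITIAL)
        d1 = ms.direct_evidence(values, prior)
        perm = np.random.default_rng(3).permutation(values.shape[1])
        d2 = ms.direct_evidence(values[:, perm], prior)
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_underdetermined_conditioning_warns_and_stays_bounded(self, caplog):
        rng = np.random.default_rng(5)
        p, m, n = 12, 8, 4  # conditioning sets wider than n - 2
        values = rng.standard_normal((p, n))
        names = [f"TF{i}" for i in range(m)] + [f"G{j}" for j in range(p - m)]
        M = np.zeros((p, m), dtype=int)
        M[m:, :] = 1
        prior = make_prior(M, names[:m], names)
        with caplog.at_level("WARNING"):
            d = ms.direct_evidence(values, prior)
        assert "minimum-norm" in caplog.text
        assert np.isfinite(d).all() and (d >= 0).all() and (d <= 1).all()


def penalized_logistic_oracle(design, y, penalty):
    """BFGS minimization of the penalized negative log-likelihood."""
    pen = np.full(design.shape[1], penalty)
    pen[0] = 0.0

    def nll(beta):
        eta = design @ beta
        return np.sum(np.logaddexp(0, eta) - y * eta) + 0.5 * np.sum(pen * beta ** 2)

    def grad(beta):
        mu = 1 / (1 + np.exp(-design @ beta))
        return design.T @ (mu - y) + pen * beta

    res = minimize(nll, np.zeros(design.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    return 1 / (1 + np.exp(-design @ res.x))


class TestIndirectEvidence:
    def test_constant_response_column(self, caplog):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((6, 5))
        prior = make_prior(np.ones((6, 1), dtype=int), ["TF1"],
                           ["TF1"] + [f"G{j}" for j in range(5)])
        with caplog.at_level("WARNING"):
            theta = ms.indirect_evidence(values, prior)
        assert np.all(theta[:, 0] >= 0.99)
        assert "constant" in caplog.text

    def test_constant_predictors_give_prevalence(self):
        values = np.ones((8, 4))  # every sample constant across genes
        M = np.zeros((8, 1), dtype=int)
        M[:3, 0] = 1
        prior = make_prior(M, ["TF1"], [f"g{j}" for j in range(8)])
        theta = ms.indirect_evidence(values, prior)
        np.testing.assert_allclose(theta[:, 0], 3 / 8, atol=1e-8)

    def test_matches_penalized_irls_oracle(self):
        rng = np.random.default_rng(9)
        p, n = 8, 3
        values = rng.standard_normal((p, n))
        M = np.zeros((p, 2), dtype=int)
        M[[0, 2, 5], 0] = 1
        M[[1, 2, 3, 6], 1] = 1
        prior = make_prior(M, ["TF1", "TF2"], [f"g{j}" for j in range(p)])
        theta = ms.indirect_evidence(values, prior)
        standardized = (values - values.mean(0)) / values.std(0)
        design = np.hstack([np.ones((p, 1)), standardized])
        for i in range(2):
            expected = penalized_logistic_oracle(design, M[:, i].astype(float),
                                                 LOGISTIC_PENALTY)
            np.testing.assert_allclose(theta[:, i], expected, atol=1e-8)

    def test_column_means_reproduce_prevalence(self, small_dataset):
        expr, prior, _ = small_dataset
        theta = ms.indirect_evidence(expr.subset_values(GROUP_INITIAL), prior)
        prevalence = prior.M.mean(axis=0)
        np.testing.assert_allclose(theta.mean(axis=0), prevalence, atol=1e-4)


class TestCombineEvidence:
    def test_endpoints(self, rng):
        d = rng.uniform(size=(12, 3))
        t = rng.uniform(size=(12, 3))
        np.testing.assert_allclose(ms.combine_evidence(d, t, 0.0), rank_normalize(d))
        np.testing.assert_allclose(ms.combine_evidence(d, t, 1.0), rank_normalize(t))

    def test_hand_worked_ranks(self):
        d = np.array([[0.9], [0.1], [0.5]])
        t = np.array([[0.2], [0.8], [0.5]])
        w = ms.combine_evidence(d, t, 0.5)
        np.testing.assert_allclose(w[:, 0], [2 / 3, 2 / 3, 2 / 3], atol=1e-12)

    def test_alpha_out_of_range(self):
        d = np.zeros((3, 1))
        with pytest.raises(ValueError, match="alpha"):
            ms.combine_evidence(d, d, 1.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.sampled_from([np.exp, np.cbrt, lambda x: 3 * x + 1]))
    def test_invariant_to_monotone_transforms(self, seed, transform):
        rng = np.random.default_rng(seed)
        d = rng.uniform(size=(10, 2))
        t = rng.uniform(size=(10, 2))
        base = ms.combine_evidence(d, t, 0.5)
        np.testing.assert_allclose(
            ms.combine_evidence(transform(d), t, 0.5), base, atol=1e-12)
        np.testing.assert_allclose(
            ms.combine_evidence(d, transform(t), 0.5), base, atol=1e-12)

    def test_rank_normalized_weights_in_unit_interval(self, small_dataset):
        expr, prior, _ = small_dataset
        net = ms.infer_network(expr, prior, GROUP_INITIAL)
        assert (net.weights > 0).all() and (net.weights <= 1).all()


class TestInferNetwork:
    def test_deterministic_and_default_alpha(self, small_dataset):
        expr, prior, _ = small_dataset
        n1 = ms.infer_network(expr, prior, GROUP_INITIAL)
        n2 = ms.infer_network(expr, prior, GROUP_INITIAL)
        np.testing.assert_array_equal(n1.weights, n2.weights)
        assert n1.alpha == 0.5

    def test_identical_sample_subsets_give_identical_networks(self, small_dataset):
        expr, prior, _ = small_dataset
        flipped = {s: (GROUP_FINAL if g == GROUP_INITIAL else GROUP_INITIAL)
                   for s, g in expr.group_of.items()}
        n1 = ms.infer_network(expr, prior, GROUP_INITIAL)
        n2 = ms.infer_network(expr.with_groups(flipped), prior, GROUP_FINAL)
        np.testing.assert_array_equal(n1.weights, n2.weights)

    def test_true_targets_rank_above_non_targets(self, small_dataset):
        expr, prior, _ = small_dataset
        net = ms.infer_network(expr, prior, GROUP_INITIAL)
        target_mask = prior.M.astype(bool)
        assert net.weights[target_mask].mean() > net.weights[~target_mask].mean()
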