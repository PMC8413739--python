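"""Covariate residualization, partial-correlation networks, thresholding."""

import numpy as np
import pytest

from scnet import (
    NetworkConstructionError,
    apply_weight_policy,
    partial_correlation_network,
    residualize,
    threshold_by_density,
)
from _oracles import oracle_partial_correlation


def _orthogonalize(volumes, age, sex):
    """Make volume columns exactly orthogonal to the covariates in-sample
    (residualize them on [1, age, sex]) while keeping a positive mean."""
    X = np.column_stack([np.ones(len(age)), age, sex])
    beta, *_ = np.linalg.lstsq(X, volumes, rcond=None)
    return volumes - X @ beta + 0.5


class TestResidualize:
    def test_exact_linear_effect_gives_zero_residuals(self, make_cohort):
        rng = np.random.default_rng(0)
        age = rng.uniform(18, 35, 12)
        volumes = np.tile(2.0 * age[:, None], (1, 56))
        cohort = make_cohort(volumes, age, rng.integers(0, 2, 12),
                             ["a"] * 12)
        resid = residualize(cohort, ("age",), group="a")
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_covariates_reduce_to_centering(self, make_cohort):
        rng = np.random.default_rng(1)
        age = rng.uniform(18, 35, 14)
        sex = rng.integers(0, 2, 14)
        volumes = _orthogonalize(rng.normal(0.5, 0.05, (14, 56)), age, sex)
        cohort = make_cohort(volumes, age, sex, ["a"] * 14)
        resid = residualize(cohort, ("age", "sex"), group="a")
        np.testing.assert_allclose(resid, volumes - volumes.mean(axis=0),
                                   atol=1e-12)

    def test_matches_normal_equations_oracle(self, make_cohort):
        rng = np.random.default_rng(2)
        n = 10
        age = rng.uniform(18, 35, n)
        sex = rng.integers(0, 2, n)
        volumes = rng.normal(0.5, 0.08, (n, 56))
        cohort = make_cohort(volumes, age, sex, ["a"] * n)
        resid = residualize(cohort, ("age", "sex"), group="a")
        X = np.column_stack([np.ones(n), age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ volumes)
        np.testing.assert_allclose(resid, volumes - X @ beta, atol=1e-10)
        assert np.abs(resid.mean(axis=0)).max() < 1e-10

    def test_constant_covariate_is_named(self, make_cohort):
        cohort = make_cohort(np.random.default_rng(3).normal(0.5, 0.05,
                                                             (8, 56)),
                             age=np.linspace(20, 30, 8),
                             sex=np.ones(8, dtype=int), groups=["a"] * 8)
        with pytest.raises(NetworkConstructionError, match="'sex'"):
            residualize(cohort, ("age", "sex"), group="a")

    def test_requires_normalized_cohort(self, small_cohort):
        with pytest.raises(NetworkConstructionError, match="normalized"):
            residualize(small_cohort, ("age",), group="patients")


class TestPartialCorrelationNetwork:
    def test_reduces_to_pearson_for_orthogonal_covariates(self, make_cohort):
        rng = np.random.default_rng(4)
        n = 20
        age = rng.uniform(18, 35, n)
        sex = rng.integers(0, 2, n)
        volumes = _orthogonalize(rng.normal(0.5, 0.05, (n, 56)), age, sex)
        cohort = make_cohort(volumes, age, sex, ["a"] * n)
        net = partial_correlation_network(cohort, "a", ("age", "sex"),
                                          weight_policy="keep")
        plain = np.corrcoef(volumes, rowvar=False)
        np.fill_diagonal(plain, 0.0)
        np.testing.assert_allclose(net.weights, plain, atol=1e-10)

    def test_matches_recursive_formula_oracle(self, make_cohort):
        rng = np.random.default_rng(5)
        n = 50
        age = rng.uniform(18, 35, n)
        sex = rng.integers(0, 2, n).astype(float)
        base = rng.normal(size=n)
        volumes = np.column_stack([
            0.5 + 0.01 * base + 0.002 * age + rng.normal(0, 0.01, n),
            0.5 + 0.008 * base + 0.05 * sex + rng.normal(0, 0.01, n),
            0.5 + rng.normal(0, 0.01, n) - 0.001 * age,
        ])
        cohort = make_cohort(volumes, age, sex.astype(int), ["a"] * n)
        net = partial_correlation_network(cohort, "a", ("age", "sex"),
                                          weight_policy="keep")
        for i in range(3):
            for j in range(i + 1, 3):
                expected = oracle_partial_correlation(
                    volumes[:, i], volumes[:, j], age, sex)
                assert net.weights[i, j] == pytest.approx(expected,
                                                          abs=1e-10)

    def test_duplicated_region_has_unit_edge(self, make_cohort):
        rng = np.random.default_rng(6)
        n = 15
        v = rng.normal(0.5, 0.05, (n, 2))
        volumes = np.column_stack([v[:, 0], v[:, 0], v[:, 1]])
        cohort = make_cohort(volumes, rng.uniform(18, 35, n),
                             rng.integers(0, 2, n), ["a"] * n)
        net = partial_correlation_network(cohort, "a")
        assert net.weights[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert net.weights[0, 0] == 0.0

    def test_zero_variance_region_is_named(self, make_cohort):
        rng = np.random.default_rng(7)
        n = 12
        volumes = rng.normal(0.5, 0.05, (n, 56))
        volumes[:, 0] = 0.4  # constant region -> zero residual variance
        cohort = make_cohort(volumes, rng.uniform(18, 35, n),
                             rng.integers(0, 2, n), ["a"] * n)
        with pytest.raises(NetworkConstructionError,
                           match="left_anterior-amygdala-area"):
            partial_correlation_network(cohort, "a")

    def test_affine_rescaling_invariance(self, make_cohort):
        rng = np.random.default_rng(8)
        n = 18
        age = rng.uniform(18, 35, n)
        sex = rng.integers(0, 2, n)
        volumes = rng.normal(0.5, 0.05, (n, 56))
        scaled = volumes.copy()
        scaled[:, 3] = 7.5 * scaled[:, 3] + 0.2  # affine map of one region
        net1 = partial_correlation_network(
            make_cohort(volumes, age, sex, ["a"] * n), "a")
        net2 = partial_correlation_network(
            make_cohort(scaled, age, sex, ["a"] * n), "a")
        np.testing.assert_allclose(net1.weights, net2.weights, atol=1e-12)

    def test_output_exactly_symmetric(self, study_cohort):
        net = partial_correlation_network(study_cohort, "patients")
        assert np.array_equal(net.weights, net.weights.T)
        assert (np.diag(net.weights) == 0).all()
        assert net.weights.min() >= 0 and net.weights.max() <= 1

    def test_too_few_subjects_rejected(self, make_cohort):
        rng = np.random.default_rng(9)
        cohort = make_cohort(rng.normal(0.5, 0.05, (4, 56)),
                             [20, 22, 24, 26], [0, 1, 0, 1], ["a"] * 4)
        with pytest.raises(NetworkConstructionError, match="at least 5"):
            partial_correlation_network(cohort, "a")


class TestWeightPolicy:
    @pytest.mark.parametrize(
        "policy,inp,expected",
        [("zero_negative", -0.3, 0.0), ("absolute", -0.3, 0.3),
         ("keep", -0.3, -0.3)],
    )
    def test_policies(self, policy, inp, expected):
        w = np.array([[0.0, inp], [inp, 0.0]])
        out = apply_weight_policy(w, policy)
        assert out[0, 1] == expected

    def test_keep_only_zeroes_diagonal(self):
        rng = np.random.default_rng(10)
        w = rng.uniform(-1, 1, (6, 6))
        w = (w + w.T) / 2
        out = apply_weight_policy(w, "keep")
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_array_equal(out[off], w[off])
        assert (np.diag(out) == 0).all()

    def test_unknown_policy_rejected(self):
        with pytest.raises(NetworkConstructionError, match="clip"):
            apply_weight_policy(np.zeros((2, 2)), "clip")


class TestThresholdByDensity:
    def _toy(self):
        w = np.zeros((4, 4))
        weights = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.1, (1, 2): 0.7,
                   (1, 3): 0.3, (2, 3): 0.5}
        for (i, j), v in weights.items():
            w[i, j] = w[j, i] = v
        return w

    def test_keeps_exactly_top_k(self):
        binary = threshold_by_density(self._toy(), 0.5)
        assert binary.n_edges == 3
        # oracle: sort the 6 weights, keep the 3 strongest
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert binary.adjacency[i, j] == 1
        for i, j in [(0, 3), (1, 3), (2, 3)]:
            assert binary.adjacency[i, j] == 0

    def test_saturation_returns_support(self):
        w = self._toy()
        w[0, 3] = w[3, 0] = 0.0  # only 5 positive edges
        binary = threshold_by_density(w, 0.9)  # asks for 5 of 6
        np.testing.assert_array_equal(binary.adjacency, (w > 0).astype(int))

    def test_all_ties_are_deterministic(self):
        w = np.ones((5, 5)) - np.eye(5)
        b1 = threshold_by_density(w, 0.5)
        b2 = threshold_by_density(w, 0.5)
        np.testing.assert_array_equal(b1.adjacency, b2.adjacency)
        assert b1.n_edges == 5  # round(0.5 * 10)
        # lexicographic tie rule: first pairs in (i, j) order win
        expected = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2)]
        assert [(i, j) for i, j in zip(*np.nonzero(np.triu(b1.adjacency)))
                ] == expected

    def test_nested_edge_sets_along_density_grid(self, study_cohort):
        net = partial_correlation_network(study_cohort, "patients")
        previous = None
        for density in np.arange(0.1, 1.0, 0.1):
            adj = threshold_by_density(net, float(density)).adjacency
            if previous is not None:
                assert ((previous == 1) <= (adj == 1)).all()
            previous = adj

    def test_degenerate_densities_rejected(self):
        with pytest.raises(NetworkConstructionError, match="0 edges"):
            threshold_by_density(np.ones((3, 3)) - np.eye(3), 0.05)
        with pytest.raises(NetworkConstructionError, match="density"):
            threshold_by_density(self._toy(), 1.5)

    def test_requesting_more_than_positive_warns(self, caplog):
        w = self._toy()
        w[w < 0.6] = 0.0  # 3 positive edges
        import logging

        with caplog.at_level(logging.WARNING, logger="scnet.networks"):
            binary = threshold_by_density(w, 0.9)
        assert binary.n_edges == 3
        assert any("positive" in rec.message for rec in caplog.records)

    def test_negative_weights_rejected(self):
        w = self._toy()
        w[0, 1] = w[1, 0] = -0.2
        with pytest.raises(NetworkConstructionError, match="non-negative"):
            threshold_by_density(w, 0.5)
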