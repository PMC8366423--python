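"""Fisher-information machinery: Jacobian, FI matrix vs the exact Poisson
KL oracle, uncertainty extraction, ellipses, likelihood, fitting and the
Metropolis-Hastings cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nrfisher as nf
from nrfisher.fisher import SingularFisherMatrix

from conftest import one_layer_fixture, table1_parameter_set


def make_dataset(q, incident, r=None, dr=None, counts=None):
    q = np.asarray(q, dtype=float)
    incident = np.asarray(incident, dtype=float)
    if r is None:
        r = np.ones_like(q)
    if dr is None:
        dr = np.full_like(q, 0.1)
    return nf.ReflectivityDataset(
        q=q, r=r, dr=dr, incident=incident, counts=counts
    )


class ScalarModel:
    """Toy model r(Q) = xi at every Q, plus an inert spare attribute."""

    def __init__(self, xi):
        self.xi = xi
        self.unused = 1.0

    def reflectivity(self, q):
        return np.full(np.shape(q), self.xi)


class ExpModel:
    """Toy model r(Q) = a exp(-Q): linear in a, so the finite-difference
    derivative is exact up to rounding."""

    def __init__(self, a):
        self.a = a

    def reflectivity(self, q):
        return self.a * np.exp(-np.asarray(q))


class TestJacobian:
    def test_inert_parameter_gives_zero_column(self):
        model = ScalarModel(0.5)
        ds = make_dataset([0.1, 0.2], [1e3, 1e3])
        params = nf.ParameterSet(
            [
                nf.Parameter("xi", [(model, "xi")], (0.1, 1.0)),
                nf.Parameter("inert", [(model, "unused")], (0.5, 2.0)),
            ]
        )
        J = nf.jacobian([model], [ds], params)
        assert np.array_equal(J[:, 1], np.zeros(2))
        assert J[:, 0] == pytest.approx([1.0, 1.0])

    def test_linear_model_derivative_is_exact(self):
        model = ExpModel(2.0)
        q = np.linspace(0.01, 0.3, 25)
        ds = make_dataset(q, np.full(q.size, 1e4))
        params = nf.ParameterSet([nf.Parameter("a", [(model, "a")], (1.0, 3.0))])
        J = nf.jacobian([model], [ds], params)
        assert J[:, 0] == pytest.approx(np.exp(-q), rel=1e-6)

    def test_film_thickness_column_oscillates(self, table1, flux):
        """Perturbing the Cu thickness moves the Kiessig fringes, so the
        derivative alternates sign across Q."""
        cond = nf.MeasurementCondition(angle=2.0, time=100.0, n_points=60)
        ds = nf.expected_counts(table1, flux, cond)
        cu = table1.structure.layers[1]
        params = nf.ParameterSet(
            [nf.Parameter("cu_thick", [(cu, "thickness")], (200.0, 400.0))]
        )
        J = nf.jacobian([table1], [ds], params)
        signs = np.sign(J[:, 0])
        flips = np.sum(signs[:-1] * signs[1:] < 0)
        assert flips >= 2


class TestFisherMatrix:
    def test_scalar_poisson_information(self):
        """r(xi) = xi with incident s: the Poisson FI of mean s*xi is s/xi."""
        model = ScalarModel(0.5)
        s = 1.0e4
        ds = make_dataset([0.1], [s])
        params = nf.ParameterSet([nf.Parameter("xi", [(model, "xi")], (0.1, 1.0))])
        an = nf.fisher_matrix([model], [ds], params)
        assert an.g[0, 0] == pytest.approx(s / 0.5, rel=1e-9)
        # cross-check against the curvature of the exact Poisson KL
        h = 1e-4
        d_plus = nf.kl_divergence_counts([model], [ds], params, [0.5 + h])
        d_minus = nf.kl_divergence_counts([model], [ds], params, [0.5 - h])
        curvature = (d_plus + d_minus) / h**2
        assert an.g[0, 0] == pytest.approx(curvature, rel=1e-4)

    def test_doubling_counts_doubles_information(self, table1, flux):
        cond = nf.MeasurementCondition(angle=0.7, time=450.0, n_points=40)
        ds = nf.expected_counts(table1, flux, cond)
        ds2 = nf.ReflectivityDataset(
            q=ds.q, r=ds.r, dr=ds.dr, incident=2.0 * ds.incident, counts=ds.counts
        )
        params = table1_parameter_set(table1)
        g1 = nf.fisher_matrix([table1], [ds], params).g
        g2 = nf.fisher_matrix([table1], [ds2], params).g
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-12)

    def test_time_scaling_is_exact(self, table1, flux):
        params = table1_parameter_set(table1)
        c1 = nf.MeasurementCondition(angle=0.7, time=450.0, n_points=40)
        c9 = nf.MeasurementCondition(angle=0.7, time=9 * 450.0, n_points=40)
        g1 = nf.fisher_matrix([table1], [nf.expected_counts(table1, flux, c1)], params).g
        g9 = nf.fisher_matrix([table1], [nf.expected_counts(table1, flux, c9)], params).g
        np.testing.assert_allclose(g9, 9.0 * g1, rtol=1e-12)
        e1 = nf.parameter_uncertainties(g1)
        e9 = nf.parameter_uncertainties(g9)
        np.testing.assert_allclose(e9, e1 / 3.0, rtol=1e-9)

    def test_disjoint_parameters_give_block_structure(self):
        m1, m2 = ExpModel(2.0), ExpModel(3.0)
        q = np.linspace(0.01, 0.2, 10)
        d1 = make_dataset(q, np.full(q.size, 1e4))
        d2 = make_dataset(q, np.full(q.size, 1e4))
        params = nf.ParameterSet(
            [
                nf.Parameter("a1", [(m1, "a")], (1.0, 3.0)),
                nf.Parameter("a2", [(m2, "a")], (2.0, 4.0)),
            ]
        )
        an = nf.fisher_matrix([m1, m2], [d1, d2], params)
        assert an.g[0, 1] == 0.0 and an.g[1, 0] == 0.0
        g_single = nf.fisher_matrix(
            [m1], [d1], nf.ParameterSet([nf.Parameter("a1", [(m1, "a")], (1.0, 3.0))])
        ).g
        assert an.g[0, 0] == pytest.approx(g_single[0, 0], rel=1e-12)

    def test_nonpositive_reflectance_rejected(self):
        model = ScalarModel(0.0)
        ds = make_dataset([0.1], [1e3])
        params = nf.ParameterSet([nf.Parameter("xi", [(model, "xi")], (-1.0, 1.0))])
        with pytest.raises(ValueError, match="reflectance"):
            nf.fisher_matrix([model], [ds], params)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), n_layers=st.integers(1, 3))
    def test_fisher_matrix_is_symmetric_psd(self, flux, seed, n_layers):
        structure = nf.random_structure(n_layers, seed=seed)
        model = nf.ReflectivityModel(
            structure, scale=1.0, background=1e-6, resolution_dq_q=0.02
        )
        cond = nf.MeasurementCondition(angle=0.7, time=450.0, n_points=50)
        ds = nf.expected_counts(model, flux, cond)
        layer = structure.layers[0]
        params = nf.ParameterSet(
            [
                nf.Parameter("t", [(layer, "thickness")], None),
                nf.Parameter("rho", [(layer, "sld")], None),
            ]
        )
        g = nf.fisher_matrix([model], [ds], params).g
        assert np.array_equal(g, g.T)
        evals = np.linalg.eigvalsh(g)
        assert np.all(evals >= -1e-8 * np.abs(evals).max())


class TestKLOracle:
    def test_zero_displacement_is_zero(self):
        model = ScalarModel(0.5)
        ds = make_dataset([0.1], [1e3])
        params = nf.ParameterSet([nf.Parameter("xi", [(model, "xi")], (0.1, 1.0))])
        assert nf.kl_divergence_counts([model], [ds], params, [0.5]) == 0.0

    def test_single_bin_closed_form(self):
        want = 100.0 * np.log(100.0 / 110.0) - 100.0 + 110.0
        assert nf.poisson_kl([100.0], [110.0]) == pytest.approx(want)
        assert want == pytest.approx(0.46898, abs=1e-5)

    def test_quadratic_expansion_matches_exact_kl(self, table1, table1_expected):
        """D(xi || xi + Delta) ~ 1/2 Delta' g Delta for small Delta."""
        params = table1_parameter_set(table1)
        an = nf.fisher_matrix([table1, table1], table1_expected, params)
        delta = 0.1 * an.uncertainties
        d_exact = nf.kl_divergence_counts(
            [table1, table1], table1_expected, params, params.values + delta
        )
        d_quad = 0.5 * delta @ an.g @ delta
        assert abs(d_exact - d_quad) / d_exact < 1e-2


class TestUncertainties:
    def test_diagonal_matrix(self):
        assert nf.parameter_uncertainties(np.diag([4.0, 25.0])) == pytest.approx(
            [0.5, 0.2]
        )

    def test_hand_inverted_two_by_two(self):
        g = np.array([[2.0, 1.0], [1.0, 1.0]])
        assert nf.parameter_uncertainties(g) == pytest.approx([1.0, np.sqrt(2.0)])

    def test_scaling_law(self):
        g = np.array([[2.0, 1.0], [1.0, 1.0]])
        e1 = nf.parameter_uncertainties(g)
        e4 = nf.parameter_uncertainties(4.0 * g)
        assert e4 == pytest.approx(e1 / 2.0)

    def test_singular_matrix_names_degenerate_combination(self):
        g = np.array([[1.0, 1.0], [1.0, 1.0]])  # perfectly correlated
        with pytest.raises(SingularFisherMatrix, match="p0"):
            nf.parameter_uncertainties(g)


class TestConfidenceEllipse:
    @staticmethod
    def _analysis():
        m1, m2 = ExpModel(2.0), ExpModel(3.0)
        q = np.linspace(0.01, 0.2, 10)
        ds = make_dataset(q, np.full(q.size, 1e4))
        params = nf.ParameterSet(
            [
                nf.Parameter("a1", [(m1, "a")], (1.0, 3.0)),
                nf.Parameter("a2", [(m2, "a")], (2.0, 4.0)),
            ]
        )
        return nf.fisher_matrix([m1, m2], [ds, ds], params)

    def test_diagonal_case_is_axis_aligned(self):
        an = self._analysis()
        eps = an.uncertainties
        el = nf.confidence_ellipse(an, 0, 1, k=1.0)
        assert sorted(el.semi_axes) == pytest.approx(sorted(eps), rel=1e-9)

    def test_k_scales_linearly(self):
        an = self._analysis()
        e1 = nf.confidence_ellipse(an, 0, 1, k=1.0)
        e3 = nf.confidence_ellipse(an, 0, 1, k=3.0)
        np.testing.assert_allclose(e3.semi_axes, 3.0 * e1.semi_axes)
        b1 = e1.boundary(36) - e1.centre
        b3 = e3.boundary(36) - e3.centre
        np.testing.assert_allclose(b3, 3.0 * b1, atol=1e-15)

    def test_boundary_satisfies_quadratic_form(self, table1, table1_expected):
        params = table1_parameter_set(table1)
        an = nf.fisher_matrix([table1, table1], table1_expected, params)
        el = nf.confidence_ellipse(an, "layer1_thickness", "layer2_thickness", k=2.0)
        c_inv = np.linalg.inv(el.covariance)
        for point in el.boundary(64):
            d = point - el.centre
            assert d @ c_inv @ d == pytest.approx(4.0, abs=1e-9)


class TestLikelihood:
    def test_perfect_model_leaves_only_normalisation(self):
        q = np.array([0.01, 0.02])
        model = ScalarModel(0.5)
        ds = make_dataset(q, [1e3, 1e3], r=np.array([0.5, 0.5]), dr=np.array([0.1, 0.2]))
        want = 0.5 * np.sum(np.log(2.0 * np.pi * np.array([0.1, 0.2]) ** 2))
        assert nf.negative_log_likelihood(ds, model) == pytest.approx(want)

    def test_single_point_chi_squared(self):
        model = ScalarModel(0.5)
        ds = make_dataset([0.01], [1e3], r=np.array([1.0]), dr=np.array([0.5]))
        norm = 0.5 * np.log(2.0 * np.pi * 0.25)
        assert nf.negative_log_likelihood(ds, model) == pytest.approx(0.5 + norm)

    def test_zero_residual_point_adds_only_normalisation(self):
        model = ScalarModel(0.5)
        d1 = make_dataset([0.01], [1e3], r=np.array([1.0]), dr=np.array([0.5]))
        d2 = make_dataset(
            [0.01, 0.02], [1e3, 1e3], r=np.array([1.0, 0.5]), dr=np.array([0.5, 0.3])
        )
        delta = nf.negative_log_likelihood(d2, model) - nf.negative_log_likelihood(
            d1, model
        )
        assert delta == pytest.approx(0.5 * np.log(2.0 * np.pi * 0.09))

    def test_zero_uncertainty_rejected(self):
        model = ScalarModel(0.5)
        ds = make_dataset([0.01], [1e3], r=np.array([1.0]), dr=np.array([0.0]))
        with pytest.raises(ValueError):
            nf.negative_log_likelihood(ds, model)


class TestFit:
    def test_noise_free_recovery(self, flux):
        model, params = one_layer_fixture(seed=7)
        truth = params.values.copy()
        conds = [nf.MeasurementCondition(angle=0.7, time=450.0, n_points=50)]
        exp = [nf.expected_counts(model, flux, c) for c in conds]
        params.values = truth * 1.1  # start the bookkeeping away from truth
        res = nf.fit_model(exp, [model], params, seed=1, maxiter=80, popsize=10, tol=1e-5)
        np.testing.assert_allclose(res.values, truth, rtol=1e-3)

    def test_same_seed_gives_identical_fit(self, flux):
        model, params = one_layer_fixture(seed=3)
        cond = nf.MeasurementCondition(angle=0.7, time=450.0, n_points=40)
        ds = nf.simulate_measurement(model, flux, cond, seed=2)
        r1 = nf.fit_model([ds], [model], params, seed=11, maxiter=15, popsize=8)
        r2 = nf.fit_model([ds], [model], params, seed=11, maxiter=15, popsize=8)
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_unbounded_parameter_rejected(self, flux):
        model, params = one_layer_fixture(seed=3)
        params[0].bounds = None
        cond = nf.MeasurementCondition(angle=0.7, time=450.0, n_points=40)
        ds = nf.simulate_measurement(model, flux, cond, seed=2)
        with pytest.raises(ValueError, match="bounds"):
            nf.fit_model([ds], [model], params, seed=1)


class TestMHOracle:
    def test_flat_likelihood_recovers_uniform_prior(self):
        model = ScalarModel(0.5)
        ds = make_dataset([0.1], [1e3], r=np.array([0.4]), dr=np.array([0.1]))
        params = nf.ParameterSet(
            [nf.Parameter("inert", [(model, "unused")], (0.0, 2.0))]
        )
        model.unused = 1.0
        samples, sd = nf.mh_sampler_oracle(
            [ds], [model], params, n_steps=30_000, seed=1
        )
        assert sd[0] == pytest.approx(2.0 / np.sqrt(12.0), rel=0.1)

    def test_gaussian_target_standard_deviation(self):
        """One datum with uncertainty sigma: the posterior on the toy
        model level is N(r, sigma^2)."""
        sigma = 0.05
        model = ScalarModel(0.5)
        ds = make_dataset([0.1], [1e3], r=np.array([0.5]), dr=np.array([sigma]))
        params = nf.ParameterSet([nf.Parameter("xi", [(model, "xi")], (0.0, 1.0))])
        samples, sd = nf.mh_sampler_oracle(
            [ds], [model], params, n_steps=100_000, seed=2
        )
        assert sd[0] == pytest.approx(sigma, rel=0.1)

    def test_same_seed_gives_identical_chain(self):
        model = ScalarModel(0.5)
        ds = make_dataset([0.1], [1e3], r=np.array([0.5]), dr=np.array([0.05]))
        params = nf.ParameterSet([nf.Parameter("xi", [(model, "xi")], (0.0, 1.0))])
        s1, _ = nf.mh_sampler_oracle([ds], [model], params, n_steps=2000, seed=5)
        s2, _ = nf.mh_sampler_oracle([ds], [model], params, n_steps=2000, seed=5)
        np.testing.assert_array_equal(s1, s2)
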