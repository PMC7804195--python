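"""Density-fitting solves, reconstruction, and charge bookkeeping."""

import numpy as np
import pytest

from kdfa.basis import AuxBasis, GaussianShell, builtin_basis
from kdfa.density_fitting import (
    FitError,
    QuadratureProvider,
    AtomicDFCoefficients,
    electron_count,
    evaluate_aux_functions,
    evaluate_df_density,
    fit_density,
)
from kdfa.fixtures import quadrature_fit, synthesize_density
from kdfa.geometry import MolecularGeometry
from kdfa.grids import GridSpec


def h2_geometry(d_bohr: float) -> MolecularGeometry:
    return MolecularGeometry(["H", "H"], np.array([[0, 0, 0], [d_bohr, 0, 0]]))


@pytest.fixture(scope="module")
def s_only_basis():
    return AuxBasis({"H": [GaussianShell("H", 0, (0.8,), (1.0,))]}, name="s-only")


def aux_component(geometry, basis, index):
    """Density equal to exactly one aux function of the molecule."""

    def rho(points):
        return evaluate_aux_functions(geometry, basis, points)[:, index]

    return rho


class TestFitDensity:
    def test_identity_single_function(self, water_monomer, aux_basis, default_grid):
        """A density that IS one aux function fits to a unit coefficient vector."""
        prov = QuadratureProvider(default_grid)
        c = fit_density(water_monomer, aux_basis, prov, aux_component(water_monomer, aux_basis, 3))
        expected = np.zeros(c.flat().size)
        expected[3] = 1.0
        np.testing.assert_allclose(c.flat(), expected, atol=1e-8)
        assert c.fit_residual < 1e-8

    def test_linearity_far_separated(self, s_only_basis):
        """0.7 phi_P + 0.3 phi_R on atoms beyond Gaussian overlap -> (0.7, 0.3)."""
        geom = h2_geometry(30.0)
        prov = QuadratureProvider(GridSpec())

        def rho(points):
            phi = evaluate_aux_functions(geom, s_only_basis, points)
            return 0.7 * phi[:, 0] + 0.3 * phi[:, 1]

        c = fit_density(geom, s_only_basis, prov, rho)
        np.testing.assert_allclose(c.flat(), [0.7, 0.3], atol=1e-7)

    def test_overlapping_pair_matches_analytic_solve(self, s_only_basis):
        """Two s-Gaussians 1.5 Bohr apart: oracle = closed-form 2x2 metric solve.

        The overlap of normalized s Gaussians has the closed form
        (2 sqrt(ab)/(a+b))^(3/2) exp(-ab/(a+b) R^2); solving the 2x2 system
        with it is independent of the quadrature machinery under test.
        """
        alpha = 0.8
        r = 1.5
        geom = h2_geometry(r)
        target = np.array([0.6, 0.25])

        def rho(points):
            phi = evaluate_aux_functions(geom, s_only_basis, points)
            return phi @ target

        s12 = (2 * np.sqrt(alpha * alpha) / (2 * alpha)) ** 1.5 * np.exp(
            -alpha * alpha / (2 * alpha) * r * r
        )
        metric = np.array([[1.0, s12], [s12, 1.0]])
        b = metric @ target  # projection of the known density
        oracle = np.linalg.solve(metric, b)

        c = fit_density(geom, s_only_basis, QuadratureProvider(GridSpec()), rho)
        np.testing.assert_allclose(c.flat(), oracle, atol=1e-6)
        # and the quadrature metric itself reproduces the closed form
        m_quad = QuadratureProvider(GridSpec()).metric(geom, s_only_basis)
        np.testing.assert_allclose(m_quad, metric, atol=1e-6)

    def test_dimension_mismatch_raises(self, water_monomer, aux_basis):
        class BadProvider(QuadratureProvider):
            def projection(self, geometry, basis, source):
                return np.zeros(3)

        with pytest.raises(FitError, match="dimension"):
            fit_density(water_monomer, aux_basis, BadProvider(), lambda p: np.zeros(len(p)))


class TestEvaluateDensity:
    def test_zero_coefficients(self, water_monomer, aux_basis):
        c = AtomicDFCoefficients(
            per_atom=[np.zeros(aux_basis.n_functions(e)) for e in water_monomer.elements],
            elements=list(water_monomer.elements),
            metric="overlap",
            fit_residual=0.0,
        )
        pts = np.random.default_rng(0).normal(size=(10, 3))
        np.testing.assert_array_equal(
            evaluate_df_density(c, water_monomer, aux_basis, pts), np.zeros(10)
        )

    def test_s_function_peak_value(self):
        """Normalized s Gaussian at its center equals (2a/pi)^(3/4)."""
        alpha = 0.8
        basis = AuxBasis({"H": [GaussianShell("H", 0, (alpha,), (1.0,))]}, name="t")
        geom = MolecularGeometry(["H"], np.zeros((1, 3)))
        c = AtomicDFCoefficients([np.ones(1)], ["H"], "overlap", 0.0)
        val = evaluate_df_density(c, geom, basis, np.zeros((1, 3)))[0]
        assert val == pytest.approx((2 * alpha / np.pi) ** 0.75, rel=1e-12)

    def test_matches_bruteforce_summation(self, aux_basis):
        """Random coefficients at random points vs an explicit per-function loop."""
        rng = np.random.default_rng(4)
        geom = MolecularGeometry(
            ["O", "H"], np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.7]])
        )
        coeffs = AtomicDFCoefficients(
            [rng.normal(size=aux_basis.n_functions(e)) * 0.1 for e in geom.elements],
            list(geom.elements),
            "overlap",
            0.0,
        )
        pts = rng.normal(scale=1.5, size=(10, 3))
        # oracle: naive double loop over atoms and functions
        expected = np.zeros(10)
        for a, el in enumerate(geom.elements):
            phi = aux_basis.evaluate_element(el, pts - geom.positions[a])
            for q in range(phi.shape[1]):
                expected += coeffs.per_atom[a][q] * phi[:, q]
        np.testing.assert_allclose(
            evaluate_df_density(coeffs, geom, aux_basis, pts), expected, rtol=1e-12
        )

    def test_exact_span_reconstruction(self, water_monomer, aux_basis, default_grid):
        """A density inside the aux span is reproduced pointwise to 1e-6 relative."""
        rng = np.random.default_rng(9)
        n = sum(aux_basis.n_functions(e) for e in water_monomer.elements)
        target = rng.normal(size=n) * 0.2

        def rho(points):
            return evaluate_aux_functions(water_monomer, aux_basis, points) @ target

        c = fit_density(water_monomer, aux_basis, QuadratureProvider(default_grid), rho)
        assert c.fit_residual < 1e-8
        pts = rng.normal(scale=1.2, size=(20, 3))
        got = evaluate_df_density(c, water_monomer, aux_basis, pts)
        ref = rho(pts)
        np.testing.assert_allclose(got, ref, rtol=1e-6, atol=1e-9 * np.abs(ref).max())


class TestElectronCount:
    def test_zero_coefficients(self, aux_basis):
        c = AtomicDFCoefficients([np.zeros(aux_basis.n_functions("O"))], ["O"], "overlap", 0.0)
        assert electron_count(c, aux_basis) == 0.0

    def test_single_s_closed_form(self):
        alpha = 1.1
        shell = GaussianShell("H", 0, (alpha,), (1.0,))
        basis = AuxBasis({"H": [shell]}, name="t")
        c = AtomicDFCoefficients([np.array([2.5])], ["H"], "overlap", 0.0)
        assert electron_count(c, basis) == pytest.approx(2.5 * shell.integral_s(), rel=1e-12)

    def test_water_density_charge_within_one_percent(
        self, water_monomer, aux_basis, default_grid
    ):
        """Fit of the 10-electron synthetic water density integrates to ~10.

        Oracle: the analytic integral of the source density (sum of unit
        Gaussians times their charges).
        """
        rho = synthesize_density(water_monomer)
        assert rho.total_integral() == pytest.approx(10.0, abs=1e-12)
        c = quadrature_fit(rho, water_monomer, aux_basis, default_grid)
        assert electron_count(c, aux_basis) == pytest.approx(10.0, rel=0.01)


class TestFitProperties:
    def test_nested_basis_residual_monotone(self, water_monomer, default_grid):
        """Extending the aux basis by shells never increases the fit residual."""
        rho = synthesize_density(water_monomer)
        small = builtin_basis()
        grown = AuxBasis(
            {
                el: list(shells) + [GaussianShell(el, 0, (0.1,), (1.0,))]
                for el, shells in small.shells_by_element.items()
            },
            name="grown",
        )
        r_small = fit_density(
            water_monomer, small, QuadratureProvider(default_grid), rho
        ).fit_residual
        r_grown = fit_density(
            water_monomer, grown, QuadratureProvider(default_grid), rho
        ).fit_residual
        assert r_grown <= r_small + 1e-12

    def test_translation_leaves_coefficients_unchanged(
        self, water_monomer, aux_basis, default_grid
    ):
        rho = synthesize_density(water_monomer)
        c0 = fit_density(water_monomer, aux_basis, QuadratureProvider(default_grid), rho)
        shift = np.array([3.0, -2.0, 5.0])
        moved = water_monomer.translated(shift)
        c1 = fit_density(
            moved, aux_basis, QuadratureProvider(default_grid), rho.translated(shift)
        )
        np.testing.assert_allclose(c0.flat(), c1.flat(), atol=1e-8)
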