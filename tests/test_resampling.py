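"""Proton-transfer coordinates, Boltzmann reweighting, and binned free energies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdfa.geometry import MolecularGeometry
from kdfa.resampling import (
    EnsembleError,
    EnsembleRecord,
    effective_sample_size,
    fes_2d,
    proton_coordinates,
    resample,
    rsm_weights,
)
from kdfa.units import KB_MEV, MEV_TO_HARTREE


def zundel_like(h_shared_x: float, r_oo: float = 2.45) -> MolecularGeometry:
    """Two oxygens on the x axis plus the shared proton at the given x."""
    pos = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oo, 0.0, 0.0],
            [h_shared_x, 0.0, 0.0],
            [-0.33, 0.92, 0.0],
            [-0.33, -0.46, 0.80],
            [r_oo + 0.33, 0.92, 0.0],
            [r_oo + 0.33, -0.46, -0.80],
        ]
    )
    return MolecularGeometry.from_angstrom(
        ["O", "O", "H", "H", "H", "H", "H"], pos, total_charge=1
    )


class TestProtonCoordinates:
    def test_symmetric_dimer_has_nu_zero(self):
        r_oo, nu = proton_coordinates(zundel_like(1.225))
        assert nu == pytest.approx(0.0, abs=1e-12)

    def test_r_oo_is_oxygen_separation(self):
        r_oo, _ = proton_coordinates(zundel_like(1.0, r_oo=2.45))
        assert r_oo == pytest.approx(2.45, abs=1e-12)

    def test_displaced_proton_sign_convention(self):
        """H at 1.0 A from O1 and 1.5 A from O2 gives nu = -0.5 A."""
        _, nu = proton_coordinates(zundel_like(1.0, r_oo=2.5))
        assert nu == pytest.approx(-0.5, abs=1e-12)

    def test_wrong_oxygen_count_rejected(self):
        water = MolecularGeometry.from_angstrom(
            ["O", "H", "H"], np.array([[0, 0, 0], [0.96, 0, 0], [0, 0.96, 0]])
        )
        with pytest.raises(EnsembleError, match="exactly 2 oxygens"):
            proton_coordinates(water)


class TestRsmWeights:
    def test_constant_shift_gives_uniform_weights(self):
        e = np.linspace(-2.0, 1.0, 40)
        w = rsm_weights(e, e + 0.05, 300.0)
        np.testing.assert_allclose(w, np.full(40, 1 / 40), rtol=1e-12)
        assert effective_sample_size(w) == pytest.approx(40.0, rel=1e-12)

    def test_kbt_ln2_gap_gives_two_to_one_ratio(self):
        t = 300.0
        gap = KB_MEV * t * np.log(2.0) * MEV_TO_HARTREE
        w = rsm_weights(np.zeros(2), np.array([0.0, gap]), t)
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-12)

    def test_matches_naive_exponentiation(self):
        rng = np.random.default_rng(11)
        de = rng.normal(scale=5e-4, size=5)  # Hartree
        t = 350.0
        w = rsm_weights(np.zeros(5), de, t)
        kbt = KB_MEV * t * MEV_TO_HARTREE
        naive = np.exp(-de / kbt)
        naive /= naive.sum()
        np.testing.assert_allclose(w, naive, rtol=1e-12)

    def test_overflow_safe_for_huge_gaps(self):
        w = rsm_weights(np.zeros(3), np.array([0.0, -50.0, 50.0]), 300.0)
        assert np.all(np.isfinite(w))
        assert w[1] == pytest.approx(1.0)

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(EnsembleError):
            rsm_weights(np.array([0.0, np.nan]), np.zeros(2), 300.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=-1.0, max_value=1.0),
    )
    def test_shift_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        e_low = rng.normal(scale=1e-3, size=8)
        e_high = e_low + rng.normal(scale=1e-3, size=8)
        w0 = rsm_weights(e_low, e_high, 300.0)
        w1 = rsm_weights(e_low + shift, e_high, 300.0)
        w2 = rsm_weights(e_low, e_high + shift, 300.0)
        np.testing.assert_allclose(w0, w1, rtol=1e-9)
        np.testing.assert_allclose(w0, w2, rtol=1e-9)


class TestResample:
    def test_single_frame_always_drawn(self):
        np.testing.assert_array_equal(resample(np.array([1.0]), 20, 0), np.zeros(20))

    def test_zero_weight_frame_never_drawn(self):
        draws = resample(np.array([1.0, 0.0]), 500, 3)
        assert np.all(draws == 0)

    def test_frequencies_converge_to_weights(self):
        """Fair coin at n = 1e5: each frequency within the 5-sigma binomial band."""
        n = 100_000
        draws = resample(np.array([0.5, 0.5]), n, 12)
        freq = np.mean(draws == 0)
        sigma = np.sqrt(0.25 / n)
        assert abs(freq - 0.5) < 5 * sigma

    def test_reproducible_under_seed(self):
        w = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(resample(w, 100, 7), resample(w, 100, 7))

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(EnsembleError):
            resample(np.array([0.5, 0.4]), 10, 0)


class TestEffectiveSampleSize:
    def test_uniform_gives_n(self):
        assert effective_sample_size(np.full(100, 0.01)) == pytest.approx(100.0)

    def test_one_hot_gives_one(self):
        w = np.zeros(10)
        w[3] = 1.0
        assert effective_sample_size(w) == pytest.approx(1.0)

    def test_direct_formula(self):
        assert effective_sample_size(np.array([0.75, 0.25])) == pytest.approx(1.6)


def _records(r_vals, nu_vals):
    return [
        EnsembleRecord(f"f{i}", 0.0, 0.0, r, nu)
        for i, (r, nu) in enumerate(zip(r_vals, nu_vals))
    ]


class TestFes2d:
    def test_uniform_occupation_gives_flat_surface(self):
        rs = [2.41, 2.41, 2.43, 2.43]
        nus = [-0.01, 0.01, -0.01, 0.01]
        grid = fes_2d(_records(rs, nus), temperature=300.0)
        occupied = ~np.isnan(grid.free_energy_mev)
        np.testing.assert_allclose(grid.free_energy_mev[occupied], 0.0, atol=1e-10)

    def test_probability_ratio_e_gives_kbt_gap(self):
        """Two bins with P ratio e differ by exactly kB T (~25.85 meV at 300 K)."""
        n1, n2 = 1000, int(round(1000 * np.e))
        rs = [2.40] * n2 + [2.44] * n1
        nus = [0.0] * (n1 + n2)
        grid = fes_2d(_records(rs, nus), temperature=300.0)
        occupied = np.sort(grid.free_energy_mev[~np.isnan(grid.free_energy_mev)])
        expected = -KB_MEV * 300.0 * np.log(n1 / n2)
        assert occupied[0] == 0.0
        assert occupied[-1] == pytest.approx(expected, rel=2e-3)
        assert expected == pytest.approx(25.85, abs=0.05)

    def test_invariant_under_constant_e_high_shift(self):
        rng = np.random.default_rng(5)
        rs = 2.45 + rng.normal(0, 0.05, 200)
        nus = rng.normal(0, 0.1, 200)
        e_low = rng.normal(0, 1e-3, 200)
        e_high = e_low + rng.normal(0, 1e-3, 200)
        recs = _records(rs, nus)
        w0 = rsm_weights(e_low, e_high, 300.0)
        w1 = rsm_weights(e_low, e_high + 0.42, 300.0)
        f0 = fes_2d(recs, w0, 300.0)
        f1 = fes_2d(recs, w1, 300.0)
        np.testing.assert_allclose(
            f0.free_energy_mev, f1.free_energy_mev, rtol=1e-9, equal_nan=True
        )

    def test_empty_bins_are_nan_not_zero(self):
        grid = fes_2d(
            _records([2.40, 2.48], [0.0, 0.0]),
            r_oo_range=(2.39, 2.49),
            nu_range=(-0.01, 0.01),
        )
        assert np.isnan(grid.free_energy_mev[2, 0])
        assert np.count_nonzero(~np.isnan(grid.free_energy_mev)) == 2

    def test_free_energy_differences_independent_of_reference(self):
        rng = np.random.default_rng(9)
        recs = _records(2.45 + rng.normal(0, 0.04, 500), rng.normal(0, 0.1, 500))
        grid = fes_2d(recs, temperature=300.0)
        f = grid.free_energy_mev
        occ = np.argwhere(~np.isnan(f))
        (i1, j1), (i2, j2) = occ[0], occ[len(occ) // 2]
        diff = f[i1, j1] - f[i2, j2]
        # re-referencing to another bin preserves pairwise differences
        shifted = f - f[i2, j2]
        assert shifted[i1, j1] - shifted[i2, j2] == pytest.approx(diff, abs=1e-12)

    def test_marginals_are_normalized_projections(self):
        rng = np.random.default_rng(2)
        recs = _records(2.45 + rng.normal(0, 0.05, 300), rng.normal(0, 0.1, 300))
        grid = fes_2d(recs)
        np.testing.assert_allclose(grid.marginal_r_oo.sum(), 1.0, rtol=1e-12)
        np.testing.assert_allclose(grid.marginal_nu.sum(), 1.0, rtol=1e-12)
        np.testing.assert_allclose(grid.marginal_r_oo, grid.probability.sum(axis=1))

    def test_min_free_energy_is_zero(self):
        rng = np.random.default_rng(3)
        recs = _records(2.45 + rng.normal(0, 0.05, 400), rng.normal(0, 0.1, 400))
        grid = fes_2d(recs)
        assert np.nanmin(grid.free_energy_mev) == 0.0

    def test_boltzmann_sampler_recovers_analytic_surface(self):
        """Reweighting samples of a harmonic surface at their own temperature
        leaves the distribution intact and the binned F matches the analytic
        quadratic within sampling noise."""
        from kdfa.fixtures import make_zundel_ensemble, surrogate_zundel_energy

        geoms, e_low = make_zundel_ensemble(20_000, temperature=300.0, seed=21)
        coords = [proton_coordinates(g) for g in geoms]
        recs = [
            EnsembleRecord(g.frame_id, el, el, r, nu)
            for g, el, (r, nu) in zip(geoms, e_low, coords)
        ]
        w = rsm_weights(e_low, e_low, 300.0)
        assert effective_sample_size(w) == pytest.approx(len(recs), rel=1e-9)
        grid = fes_2d(recs, w, 300.0, r_oo_bin_width=0.05, nu_bin_width=0.05)
        rc = 0.5 * (grid.r_oo_edges[:-1] + grid.r_oo_edges[1:])
        nc = 0.5 * (grid.nu_edges[:-1] + grid.nu_edges[1:])
        f = grid.free_energy_mev
        ana = np.array(
            [
                [surrogate_zundel_energy(r, nu) / MEV_TO_HARTREE for nu in nc]
                for r in rc
            ]
        )
        well = (grid.probability > 0.01) & ~np.isnan(f)  # >~200 expected counts
        assert well.sum() >= 10
        dev = f[well] - (ana[well] - ana[well].min())
        # bin-discretization plus sampling noise: a few meV on a ~100 meV well
        assert np.max(np.abs(dev - dev.mean())) < 6.0
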