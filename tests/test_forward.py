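"""Diffusion forward model: Green's function, homogeneous and perturbed media."""

import numpy as np
import pytest

from dotdiff import OpticalProperties, semi_infinite_green, simulate_homogeneous
from dotdiff.forward import born_perturbation, simulate_with_inclusions
from dotdiff.geometry import C_VACUUM, ForwardModelParams


def reference_image_source(source_xy, rho, props, omega):
    """Independent longhand image-source evaluation (textbook formula).

    Deliberately written from scratch (scalars, no shared code paths) as an
    oracle for the vectorized implementation.
    """
    import cmath
    import math

    D = 1.0 / (3.0 * (props.mua + props.musp))
    c = C_VACUUM / props.refractive_index
    k = cmath.sqrt((props.mua - 1j * omega / c) / D)
    if k.real < 0:
        k = -k
    n = props.refractive_index
    reff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    z0 = 1.0 / props.musp
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    r1 = math.sqrt(rho**2 + z0**2)
    r2 = math.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)
    return (cmath.exp(-k * r1) / r1 - cmath.exp(-k * r2) / r2) / (4.0 * math.pi * D)


class TestGreenFunction:
    def test_matches_longhand_image_source_formula(self, props):
        """Fixed configuration vs an independently coded textbook evaluation."""
        omega = 2 * np.pi * 140e6
        got = semi_infinite_green([0.0, 0.0, 0.0], [3.0, 0.0, 0.0], props, omega)
        want = reference_image_source(None, 3.0, props, omega)
        assert got == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_reciprocity_for_buried_points(self, props, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform([-3, -3, 0.2], [3, 3, 3])
        b = rng.uniform([-3, -3, 0.2], [3, 3, 3])
        omega = 2 * np.pi * 140e6
        g1 = semi_infinite_green(a, b, props, omega)
        g2 = semi_infinite_green(b, a, props, omega)
        assert g1 == pytest.approx(g2, rel=1e-14)

    def test_dc_limit_real_positive_and_continuous(self, props):
        g0 = semi_infinite_green([0, 0, 0], [2.5, 0, 0.5], props, 0.0)
        assert g0.imag == 0.0
        assert g0.real > 0.0
        # |G| at omega -> 0 approaches the DC value continuously
        for omega in (1e7, 1e5, 1e3):
            g = semi_infinite_green([0, 0, 0], [2.5, 0, 0.5], props, omega)
            assert abs(g - g0) < abs(
                semi_infinite_green([0, 0, 0], [2.5, 0, 0.5], props, 10 * omega) - g0
            ) + 1e-18

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(mua=-0.01, musp=7.0)
        with pytest.raises(ValueError):
            OpticalProperties(mua=0.02, musp=0.0)

    def test_singularity_raises(self, props):
        with pytest.raises(ValueError):
            semi_infinite_green([0, 0, 1.0], [0, 0, 1.0], props, 0.0)

    def test_field_point_above_surface_rejected(self, props):
        with pytest.raises(ValueError):
            semi_infinite_green([0, 0, 0], [1.0, 0, -0.5], props, 0.0)


class TestHomogeneous:
    def test_matches_per_pair_green_calls(self, geometry, props):
        meas = simulate_homogeneous(geometry, props)
        ps, pd = geometry.pair_positions()
        for i in [0, 17, 63, 125]:
            direct = semi_infinite_green(ps[i], pd[i], props, geometry.omega)
            assert meas.U[i] == pytest.approx(direct, rel=1e-14)

    @staticmethod
    def _by_unique_rho(values, rho):
        """Mean of `values` at each distinct separation, sorted ascending."""
        uniq = np.unique(np.round(rho, 9))
        return np.array(
            [values[np.isclose(rho, u)].mean() for u in uniq]
        )

    def test_amplitude_rho2_decreases_with_separation(self, geometry, props):
        meas = simulate_homogeneous(geometry, props)
        ar2 = meas.amplitude * meas.rho**2
        nd = geometry.n_detectors
        for s in range(geometry.n_sources):
            sl = slice(s * nd, (s + 1) * nd)
            curve = self._by_unique_rho(ar2[sl], meas.rho[sl])
            assert np.all(np.diff(curve) < 0)

    def test_phase_increases_with_separation(self, geometry, props):
        meas = simulate_homogeneous(geometry, props)
        nd = geometry.n_detectors
        for s in range(geometry.n_sources):
            sl = slice(s * nd, (s + 1) * nd)
            curve = self._by_unique_rho(meas.phase[sl], meas.rho[sl])
            assert np.all(np.diff(curve) > 0)

    def test_amplitude_monotone_in_absorption(self, geometry, props):
        lo = simulate_homogeneous(geometry, props)
        hi = simulate_homogeneous(
            geometry, OpticalProperties(mua=2 * props.mua, musp=props.musp)
        )
        assert np.all(hi.amplitude < lo.amplitude)


def sphere_voxels(center, radius, dmua, voxel=0.25):
    c = np.asarray(center, float)
    ax = [np.arange(c[i] - radius + voxel / 2, c[i] + radius, voxel) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts - c, axis=1) <= radius]
    return pts, voxel**3, np.full(pts.shape[0], dmua)


class TestBornInclusions:
    def test_empty_inclusions_match_homogeneous(self, geometry, props):
        meas = simulate_with_inclusions(geometry, props, [])
        base = simulate_homogeneous(geometry, props)
        np.testing.assert_allclose(meas.U, base.U, rtol=0)

    def test_absorbing_sphere_gives_negative_real_perturbation(self, geometry, props):
        inc = [sphere_voxels((0, 0, 1.5), 0.8, 0.1)]
        meas = simulate_with_inclusions(geometry, props, inc)
        base = simulate_homogeneous(geometry, props)
        pert = meas.U / base.U - 1.0
        # pairs whose midpoint sits above the sphere see a clear decrease
        ps, pd = geometry.pair_positions()
        mid = 0.5 * (ps + pd)
        above = np.linalg.norm(mid[:, :2], axis=1) < 1.5
        assert np.all(pert.real[above] < 0)

    def test_born_sum_is_linear_in_delta_mua(self, geometry, props):
        inc_full = [sphere_voxels((0.5, 0, 2.0), 0.7, 0.12)]
        inc_half = [sphere_voxels((0.5, 0, 2.0), 0.7, 0.06)]
        base = simulate_homogeneous(geometry, props)
        p_full = simulate_with_inclusions(geometry, props, inc_full).U / base.U - 1
        p_half = simulate_with_inclusions(geometry, props, inc_half).U / base.U - 1
        np.testing.assert_allclose(p_full, 2.0 * p_half, rtol=1e-12)

    def test_born_sum_additive_over_disjoint_inclusions(self, geometry, props):
        a = sphere_voxels((-1.0, 0, 1.5), 0.5, 0.1)
        b = sphere_voxels((1.5, 0, 2.5), 0.6, 0.08)
        base = simulate_homogeneous(geometry, props)
        p_ab = simulate_with_inclusions(geometry, props, [a, b]).U / base.U - 1
        p_a = simulate_with_inclusions(geometry, props, [a]).U / base.U - 1
        p_b = simulate_with_inclusions(geometry, props, [b]).U / base.U - 1
        np.testing.assert_allclose(p_ab, p_a + p_b, rtol=1e-12, atol=1e-15)

    def test_rytov_composition_exponentiates_the_same_sum(self, geometry, props):
        inc = [sphere_voxels((0, 0, 2.0), 0.8, 0.15)]
        base = simulate_homogeneous(geometry, props)
        born = simulate_with_inclusions(geometry, props, inc, composition="born")
        rytov = simulate_with_inclusions(geometry, props, inc, composition="rytov")
        p = born.U / base.U - 1.0
        np.testing.assert_allclose(rytov.U, base.U * np.exp(p), rtol=1e-12)

    def test_inclusion_above_surface_rejected(self, geometry, props):
        bad = (np.array([[0.0, 0.0, -0.5]]), 0.01, np.array([0.1]))
        with pytest.raises(ValueError):
            simulate_with_inclusions(geometry, props, [bad])

    def test_unknown_composition_rejected(self, geometry, props):
        with pytest.raises(ValueError):
            simulate_with_inclusions(geometry, props, [], composition="exact")

    def test_chunked_born_sum_matches_unchunked(self, geometry, props):
        pts, vol, dmua = sphere_voxels((0, 0, 2.0), 1.0, 0.1, voxel=0.2)
        p1 = born_perturbation(geometry, props, pts, vol, dmua, chunk=64)
        p2 = born_perturbation(geometry, props, pts, vol, dmua, chunk=10**6)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)


class TestFitBackground:
    def test_recovers_homogeneous_properties(self, geometry):
        from dotdiff import fit_background

        truth = OpticalProperties(mua=0.035, musp=6.5)
        meas = simulate_homogeneous(geometry, truth)
        fit = fit_background(meas, geometry)
        assert fit.mua == pytest.approx(truth.mua, rel=1e-4)
        assert fit.musp == pytest.approx(truth.musp, rel=1e-4)

    def test_invariant_to_coupling_gain(self, geometry):
        """Per-channel offsets are removed, so a global gain cannot bias the fit."""
        from dotdiff import fit_background
        from dotdiff.geometry import FDMeasurement

        truth = OpticalProperties(mua=0.02, musp=8.0)
        meas = simulate_homogeneous(geometry, truth)
        scaled = FDMeasurement(120.0 * meas.U, meas.rho, meas.wavelength, geometry)
        fit = fit_background(scaled, geometry)
        assert fit.mua == pytest.approx(truth.mua, rel=1e-4)
        assert fit.musp == pytest.approx(truth.musp, rel=1e-4)

    def test_shallow_chest_wall_inflates_bulk_absorption(self, geometry):
        """A shallow high-absorption wall pulls the effective bulk mua up --
        the mechanism by which a mismatched reference corrupts the operator."""
        from dotdiff import fit_background
        from dotdiff.synthdata import simulate_scene

        from conftest import make_plain_scene

        scene = make_plain_scene(bg_mua=0.02, wall=True, wall_depth=2.0)
        ref = simulate_scene(scene, geometry, include_target=False)
        fit = fit_background(ref, geometry)
        assert fit.mua > 0.03


def test_forward_params_dc_wavenumber_real(props):
    p = ForwardModelParams.from_properties(props, 0.0)
    assert p.k.imag == 0.0 and p.k.real > 0
    assert p.z0 == pytest.approx(1.0 / props.musp)
    assert p.zb > 0
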