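"""Dual mesh, Born sensitivity, Tikhonov-CG inversion, hemoglobin unmixing."""

import numpy as np
import pytest

from dotdiff import (
    assemble_sensitivity,
    build_dual_mesh,
    compute_thb,
    reconstruct,
)
from dotdiff.forward import born_perturbation, simulate_homogeneous
from dotdiff.perturbation import Perturbation, compute_perturbation, rytov_linearize
from dotdiff.reconstruction import (
    EXTINCTION,
    DualMesh,
    SensitivityMatrix,
    roi_from_target,
)
from dotdiff.synthdata import simulate_scene

from conftest import make_plain_scene

VOL = ((-4.0, 4.0), (-4.0, 4.0), (0.0, 4.0))


class TestDualMesh:
    def test_roi_covering_whole_volume_gives_all_fine(self):
        mesh = build_dual_mesh(VOL, VOL)
        assert mesh.is_fine.all()
        # 8/0.25 * 8/0.25 * 4/0.5 voxels
        assert mesh.n_voxels == 32 * 32 * 8

    def test_tiling_preserves_total_volume(self):
        mesh = build_dual_mesh(((-1, 1.2), (-0.7, 1), (1, 2.6)), VOL)
        total = mesh.volumes.sum()
        assert total == pytest.approx(8 * 8 * 4, rel=1e-9)

    def test_fine_and_coarse_disjoint(self):
        mesh = build_dual_mesh(((-1, 1), (-1, 1), (1, 2)), VOL)
        fine = mesh.centers[mesh.is_fine]
        coarse = mesh.centers[~mesh.is_fine]
        lo = np.array([b[0] for b in mesh.roi_box])
        hi = np.array([b[1] for b in mesh.roi_box])
        assert np.all((fine >= lo) & (fine <= hi))
        assert not np.any(np.all((coarse > lo) & (coarse < hi), axis=1))

    def test_voxel_counts_by_direct_enumeration(self):
        """2x2x1 cm ROI at default resolution: counts enumerated longhand."""
        mesh = build_dual_mesh(((-1, 1), (-1, 1), (1, 2)), VOL)
        n_fine = (2 / 0.25) * (2 / 0.25) * (1 / 0.5)  # 8*8*2 = 128
        n_coarse = 8 * 8 * 4 - 2 * 2 * 1  # coarse cells minus ROI cells
        assert mesh.is_fine.sum() == int(n_fine)
        assert (~mesh.is_fine).sum() == int(n_coarse)

    def test_roi_outside_volume_rejected(self):
        with pytest.raises(ValueError):
            build_dual_mesh(((-5, -4.5), (0, 1), (0, 1)), VOL)
        with pytest.raises(ValueError):
            build_dual_mesh(((1, 0), (0, 1), (0, 1)), VOL)


class TestSensitivity:
    def test_forward_consistency_with_born_kernel(self, geometry, props):
        """W @ dmua equals the Born forward perturbation to machine precision."""
        mesh = build_dual_mesh(((-1, 1), (-1, 1), (1, 2)), VOL)
        sens = assemble_sensitivity(mesh, geometry, props)
        rng = np.random.default_rng(0)
        dmua = np.where(
            np.linalg.norm(mesh.centers - [0, 0, 1.5], axis=1) < 0.8, 0.1, 0.0
        )
        direct = born_perturbation(
            geometry, props, mesh.centers, mesh.volumes, dmua,
        )
        np.testing.assert_allclose(sens.W @ dmua, direct, rtol=1e-12)

    def test_entries_finite_and_depth_attenuated(self, geometry, props):
        mesh = build_dual_mesh(((-1, 1), (-1, 1), (0.5, 3.5)), VOL)
        sens = assemble_sensitivity(mesh, geometry, props)
        assert np.all(np.isfinite(sens.W))
        fine = np.where(mesh.is_fine)[0]
        depths = mesh.centers[fine, 2]
        norms = np.linalg.norm(sens.W[:, fine], axis=0)
        # column norms decay with depth; the topmost layer is suppressed by
        # the extrapolated boundary (fluence -> 0 above the surface), so the
        # monotone decay starts from the sensitivity peak just below it
        layer_means = np.array(
            [norms[depths == z].mean() for z in np.unique(depths)]
        )
        peak = int(np.argmax(layer_means))
        assert peak <= 1
        assert np.all(np.diff(layer_means[peak:]) < 0)

    def test_column_scales_with_voxel_volume(self, geometry, props):
        centers = np.array([[0.0, 0.0, 1.5], [1.0, 0.5, 2.0]])
        base = DualMesh(
            centers=centers,
            sizes=np.full((2, 3), 0.5),
            is_fine=np.array([True, True]),
            bounds=VOL,
        )
        doubled = DualMesh(
            centers=centers,
            sizes=np.column_stack([np.full(2, 1.0), np.full(2, 0.5), np.full(2, 0.5)]),
            is_fine=np.array([True, True]),
            bounds=VOL,
        )
        W1 = assemble_sensitivity(base, geometry, props).W
        W2 = assemble_sensitivity(doubled, geometry, props).W
        np.testing.assert_allclose(W2, 2.0 * W1, rtol=1e-12)


def dense_tikhonov(W, pert, lam, comp=0.0):
    """Closed-form stacked-real Tikhonov solution (oracle)."""
    A = np.vstack([W.real, W.imag])
    b = np.concatenate([pert.real, pert.imag])
    if comp > 0:
        s = np.linalg.norm(A, axis=0) ** comp
    else:
        s = np.ones(A.shape[1])
    An = A / s
    n = An.shape[1]
    y = np.linalg.solve(An.T @ An + lam**2 * np.eye(n), An.T @ b)
    return y / s


class TestReconstruct:
    def _random_system(self, m, n, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(m, n)) + 1j * rng.normal(size=(m, n))
        pert = rng.normal(size=m) + 1j * rng.normal(size=m)
        mesh = DualMesh(
            centers=rng.uniform(-3, 3, size=(n, 3)),
            sizes=np.full((n, 3), 0.5),
            is_fine=np.ones(n, bool),
            bounds=VOL,
        )
        sens = SensitivityMatrix(W=W, mesh=mesh, background=None)
        return sens, Perturbation(pert, 785.0, "measured_matched")

    def test_zero_perturbation_gives_zero_map(self, geometry, props):
        mesh = build_dual_mesh(((-1, 1), (-1, 1), (1, 2)), VOL)
        sens = assemble_sensitivity(mesh, geometry, props)
        res = reconstruct(Perturbation(np.zeros(126, complex), 730.0), sens)
        np.testing.assert_allclose(res.delta_mua, 0.0, atol=1e-15)

    @pytest.mark.parametrize("m,n,seed", [(6, 4, 0), (40, 90, 1), (200, 500, 2)])
    def test_cg_matches_dense_closed_form(self, m, n, seed):
        """CG on the normal equations vs direct linear-algebra oracle."""
        sens, pert = self._random_system(m, n, seed)
        lam = 0.3 * np.linalg.norm(np.vstack([sens.W.real, sens.W.imag]), 2)
        res = reconstruct(pert, sens, lam=lam, depth_compensation=0.0)
        want = dense_tikhonov(sens.W, pert.values, lam, comp=0.0)
        err = np.linalg.norm(res.delta_mua - want) / np.linalg.norm(want)
        assert err <= 1e-6

    def test_compensated_path_matches_compensated_closed_form(self):
        sens, pert = self._random_system(30, 80, 3)
        A = np.vstack([sens.W.real, sens.W.imag])
        s = np.linalg.norm(A, axis=0) ** 0.5
        lam = 0.2 * np.linalg.norm(A / s, 2)
        res = reconstruct(pert, sens, lam=lam, depth_compensation=0.5)
        want = dense_tikhonov(sens.W, pert.values, lam, comp=0.5)
        err = np.linalg.norm(res.delta_mua - want) / np.linalg.norm(want)
        assert err <= 1e-6

    def test_solution_linear_in_perturbation(self):
        sens, pert = self._random_system(20, 50, 4)
        lam = 1.0
        r1 = reconstruct(pert, sens, lam=lam)
        r2 = reconstruct(
            Perturbation(3.5 * pert.values, 785.0, "measured_matched"), sens, lam=lam
        )
        np.testing.assert_allclose(r2.delta_mua, 3.5 * r1.delta_mua, rtol=1e-8)

    def test_negative_lambda_rejected(self):
        sens, pert = self._random_system(6, 4, 5)
        with pytest.raises(ValueError):
            reconstruct(pert, sens, lam=-1.0)

    def test_localization_of_buried_spheres(self, geometry):
        """1-cm spheres at 1.5-2.5 cm depth peak within one fine-voxel diagonal."""
        diag = np.sqrt(0.25**2 + 0.25**2 + 0.5**2) + 1e-9
        for depth in (1.5, 2.0, 2.5):
            scene = make_plain_scene(depth=depth, radius=1.0, target_mua=0.2)
            mesh = build_dual_mesh(roi_from_target(scene.target.center, 1.0), VOL)
            sens = assemble_sensitivity(mesh, geometry, scene.background)
            Ul = simulate_scene(scene, geometry, include_target=True)
            Ur = simulate_scene(scene, geometry, include_target=False)
            pert = rytov_linearize(compute_perturbation(Ul, Ur))
            res = reconstruct(pert, sens)
            peak = mesh.centers[np.argmax(res.delta_mua)]
            assert np.linalg.norm(peak - [0, 0, depth]) <= diag

    def test_reconstructed_contrast_monotone_in_target_mua(self, geometry):
        maxima = []
        for mua in (0.1, 0.2, 0.3):
            scene = make_plain_scene(depth=2.0, radius=1.0, target_mua=mua)
            mesh = build_dual_mesh(roi_from_target(scene.target.center, 1.0), VOL)
            sens = assemble_sensitivity(mesh, geometry, scene.background)
            Ul = simulate_scene(scene, geometry, include_target=True)
            Ur = simulate_scene(scene, geometry, include_target=False)
            res = reconstruct(rytov_linearize(compute_perturbation(Ul, Ur)), sens)
            maxima.append(res.max_mua)
        assert maxima[0] < maxima[1] < maxima[2]


class TestHemoglobin:
    def mua_from_concentrations(self, hbo2, hb):
        maps = {}
        for wl, (e_o, e_h) in EXTINCTION.items():
            maps[wl] = np.log(10.0) * 1e-6 * (e_o * hbo2 + e_h * hb)
        return maps

    def test_round_trip_recovery(self):
        rng = np.random.default_rng(0)
        hbo2 = rng.uniform(0, 60, size=(4, 5))
        hb = rng.uniform(0, 40, size=(4, 5))
        thb, rec_o, rec_h = compute_thb(self.mua_from_concentrations(hbo2, hb))
        np.testing.assert_allclose(rec_o, hbo2, rtol=1e-8, atol=1e-9)
        np.testing.assert_allclose(rec_h, hb, rtol=1e-8, atol=1e-9)
        np.testing.assert_allclose(thb, hbo2 + hb, rtol=1e-8)

    def test_zero_absorption_gives_zero_thb(self):
        maps = {wl: np.zeros((3, 3)) for wl in EXTINCTION}
        thb, _, _ = compute_thb(maps)
        np.testing.assert_array_equal(thb, 0.0)

    def test_noisy_recovery_within_propagated_bound(self):
        rng = np.random.default_rng(1)
        hbo2 = rng.uniform(10, 50, size=200)
        hb = rng.uniform(5, 30, size=200)
        maps = self.mua_from_concentrations(hbo2, hb)
        sigma = 0.002  # cm^-1 absorption noise
        noisy = {wl: m + sigma * rng.standard_normal(m.shape) for wl, m in maps.items()}
        thb, _, _ = compute_thb(noisy)
        # linear error propagation through the pseudo-inverse of E
        E = np.array([EXTINCTION[w] for w in sorted(EXTINCTION)]) * np.log(10) * 1e-6
        amp = np.linalg.norm(np.linalg.pinv(E).sum(axis=0))
        rms = np.sqrt(np.mean((thb - (hbo2 + hb)) ** 2))
        assert rms < 3 * sigma * amp

    def test_missing_wavelength_rejected(self):
        maps = {wl: np.ones((2, 2)) for wl in list(EXTINCTION)[:3]}
        with pytest.raises(ValueError):
            compute_thb(maps)
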