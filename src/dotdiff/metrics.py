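"""Image-quality metrics and the simulation test-set summary.

Covers the four quantities used to judge reconstructions: maximum
reconstructed absorption, structural similarity (SSIM) against a rendered
ground truth, the target-to-artifact ratio (peak inside a widened lesion
footprint over peak outside it), and the distance between the
reconstructed center of mass and the true lesion centroid.  Negative
reconstructed values are clipped to zero for the center-of-mass and
ratio metrics only; maps themselves are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import ProbeGeometry
from .perturbation import compute_perturbation, rytov_linearize
from .reconstruction import (
    LayeredMap,
    assemble_sensitivity,
    build_dual_mesh,
    reconstruct,
    roi_from_target,
)

SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_WIN = 7


def ssim_map(recon_layer: np.ndarray, truth_layer: np.ndarray) -> float:
    """SSIM between a reconstructed depth layer and its ground truth.

    Uniform 7x7 window (shrunk to the largest odd size that fits on small
    grids), stabilization constants K1=0.01 / K2=0.03, dynamic range taken
    from the truth image.  Symmetric in its arguments apart from the
    dynamic-range convention, which follows the truth layer.
    """
    recon = np.asarray(recon_layer, float)
    truth = np.asarray(truth_layer, float)
    if recon.shape != truth.shape:
        raise ValueError("layer shapes differ")
    dr = float(truth.max() - truth.min())
    if dr == 0:
        dr = max(float(np.abs(truth).max()), 1e-12)
    win = min(SSIM_WIN, *(s if s % 2 else s - 1 for s in truth.shape))
    return float(
        structural_similarity(
            truth,
            recon,
            win_size=win,
            data_range=dr,
            gaussian_weights=False,
            K1=SSIM_K1,
            K2=SSIM_K2,
        )
    )


def lesion_area_mask(
    layered: LayeredMap,
    centroid_xy: tuple[float, float],
    half_width_per_depth: np.ndarray,
    factor: float = 3.0,
) -> np.ndarray:
    """Per-layer lesion-area mask: lateral box of ``factor`` x the true half-width.

    ``half_width_per_depth`` gives, per depth layer, the lesion's lateral
    half-width (0 where the lesion is absent, making the whole layer
    artifact territory).
    """
    hw = np.asarray(half_width_per_depth, float)
    if hw.size != layered.values.shape[0]:
        raise ValueError("need one half-width per depth layer")
    mask = np.zeros_like(layered.values, dtype=bool)
    for iz, w in enumerate(hw):
        if w <= 0:
            continue
        inx = np.abs(layered.x - centroid_xy[0]) <= factor * w
        iny = np.abs(layered.y - centroid_xy[1]) <= factor * w
        mask[iz] = inx[:, None] & iny[None, :]
    return mask


def target_artifact_ratio(
    layered: LayeredMap,
    centroid_xy: tuple[float, float],
    half_width_per_depth: np.ndarray,
    factor: float = 3.0,
) -> float:
    """Peak inside the widened lesion area over peak outside it.

    Returns ``inf`` when everything outside is zero; raises if the lesion
    area covers the entire map (no artifact region to compare against).
    Negative values are clipped to zero first.
    """
    vals = np.clip(layered.values, 0.0, None)
    mask = lesion_area_mask(layered, centroid_xy, half_width_per_depth, factor)
    if mask.all():
        raise ValueError("lesion area covers the whole map; ratio undefined")
    inside = float(vals[mask].max()) if mask.any() else 0.0
    outside = float(vals[~mask].max())
    if outside == 0.0:
        return float("inf")
    return inside / outside


def centroid_distance(
    values: np.ndarray,
    centers: np.ndarray,
    volumes: np.ndarray,
    truth_centroid_xz: tuple[float, float],
    assume_y0: bool = True,
    blob_fraction: float = 0.5,
) -> float:
    """Distance (cm) between the reconstructed lesion's center of mass and truth.

    The reconstructed lesion is the above-half-maximum blob of the
    (negative-clipped) map -- ``blob_fraction`` of the peak; 0 uses the
    whole map.  Weights are ``value * voxel volume``; the truth centroid
    is (x, 0, z) when ``assume_y0`` (the lesion is assumed centered under
    the transducer in y), else the y term is dropped.  All-zero maps have
    no center of mass and return NaN.
    """
    v = np.clip(np.asarray(values, float), 0.0, None)
    if blob_fraction > 0 and v.max() > 0:
        v = np.where(v >= blob_fraction * v.max(), v, 0.0)
    w = v * np.asarray(volumes, float)
    total = w.sum()
    if total == 0:
        return float("nan")
    com = (np.asarray(centers, float) * w[:, None]).sum(axis=0) / total
    xt, zt = truth_centroid_xz
    dx, dz = com[0] - xt, com[2] - zt
    if assume_y0:
        return float(np.sqrt(dx**2 + com[1] ** 2 + dz**2))
    return float(np.sqrt(dx**2 + dz**2))


@dataclass
class CaseResult:
    max_mua_matched: float
    max_mua_ann: float
    abs_diff: float
    centroid_error_ann: float


@dataclass
class SummaryReport:
    """Corpus-level aggregate of the matched-vs-predicted comparison."""

    cases: list
    mean_abs_diff: float
    ci_low: float
    ci_high: float

    @property
    def n(self) -> int:
        return len(self.cases)


def _reconstruct_scene(scene, geometry, pert, lam=None):
    roi = roi_from_target(scene.target.center, scene.target.radius)
    mesh = build_dual_mesh(roi)
    sens = assemble_sensitivity(mesh, geometry, scene.background)
    return reconstruct(rytov_linearize(pert), sens, lam=lam)


def simulation_test_summary(
    test_scenes: list,
    model,
    geometry: ProbeGeometry,
    noise_fraction: float = 0.02,
    rng_seed: int = 0,
    n_bootstrap: int = 1000,
) -> SummaryReport:
    """Mean |max mua(ANN pert) - max mua(matched pert)| over held-out scenes.

    For each scene the noisy lesion-side measurement feeds the network,
    whose predicted perturbation is reconstructed on the same dual mesh
    and regularization as the matched (noise-free-reference) perturbation;
    the per-case absolute difference of the maximum reconstructed mua is
    aggregated as a mean with a seeded bootstrap 95% CI.
    """
    from .ann import predict_perturbation
    from .synthdata import _scene_measurement_pair, add_measurement_noise

    cases = []
    for scene in test_scenes:
        Ul_clean, Ur = _scene_measurement_pair(scene, geometry)
        # per-scene noise stream tied to the scene itself, so the summary is
        # invariant to case ordering
        noise_rng = np.random.default_rng([rng_seed, scene.hetero_seed])
        Ul = add_measurement_noise(Ul_clean, noise_fraction, noise_rng)
        matched = compute_perturbation(Ul_clean, Ur)
        predicted = predict_perturbation(model, Ul)

        roi = roi_from_target(scene.target.center, scene.target.radius)
        mesh = build_dual_mesh(roi)
        sens = assemble_sensitivity(mesh, geometry, scene.background)
        rec_m = reconstruct(rytov_linearize(matched), sens)
        rec_a = reconstruct(
            rytov_linearize(predicted), sens, lam=rec_m.regularization_lambda
        )
        c = scene.target.center
        cases.append(
            CaseResult(
                max_mua_matched=rec_m.max_mua,
                max_mua_ann=rec_a.max_mua,
                abs_diff=abs(rec_a.max_mua - rec_m.max_mua),
                centroid_error_ann=centroid_distance(
                    rec_a.delta_mua, mesh.centers, mesh.volumes, (c[0], c[2])
                ),
            )
        )
    rng = np.random.default_rng(rng_seed)
    diffs = np.sort([c.abs_diff for c in cases])  # sorted: CI order-invariant
    boot = np.array(
        [
            diffs[rng.integers(0, diffs.size, diffs.size)].mean()
            for _ in range(n_bootstrap)
        ]
    )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return SummaryReport(
        cases=cases,
        mean_abs_diff=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
    )
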