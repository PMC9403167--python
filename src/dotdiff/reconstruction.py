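"""Linearized image reconstruction: dual mesh, Born sensitivity, Tikhonov-CG.

The inverse problem is the regularized least-squares fit of the voxelized
absorption change to the normalized perturbation,

    min_dmua  || pert - W dmua ||^2 + lambda^2 || dmua ||^2,

with W the Born sensitivity matrix built from the same Green's-function
kernel as the simulation forward model.  Complex data are stacked as
real/imaginary blocks and the normal equations are solved by conjugate
gradient.  A dual mesh keeps the number of unknowns low: fine voxels
inside the ultrasound-indicated lesion region of interest, coarse voxels
elsewhere.

Multi-wavelength absorption maps are unmixed per voxel into oxy- and
deoxy-hemoglobin by nonnegative least squares; total hemoglobin is their
sum in micromolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.sparse.linalg import LinearOperator, cg

from .forward import green_function
from .geometry import (
    DEFAULT_VOLUME_BOUNDS,
    ForwardModelParams,
    OpticalProperties,
    ProbeGeometry,
)
from .perturbation import Perturbation

FINE_VOXEL = (0.25, 0.25, 0.5)  # cm, lesion region of interest
COARSE_VOXEL = (1.0, 1.0, 1.0)  # cm, background

#: Molar extinction coefficients (cm^-1 / M) of HbO2 and Hb at the imager's
#: wavelengths, from the standard compiled hemoglobin absorption tabulation.
EXTINCTION = {
    730.0: (390.0, 1102.2),
    785.0: (740.0, 957.2),
    808.0: (866.0, 732.0),
    830.0: (974.0, 693.04),
}


@dataclass
class DualMesh:
    """Disjoint fine (ROI) + coarse (background) voxelization of the volume."""

    centers: np.ndarray  # (n, 3) cm
    sizes: np.ndarray  # (n, 3) cm
    is_fine: np.ndarray  # (n,) bool
    bounds: tuple = DEFAULT_VOLUME_BOUNDS
    roi_box: tuple = None

    @property
    def volumes(self) -> np.ndarray:
        return np.prod(self.sizes, axis=1)

    @property
    def n_voxels(self) -> int:
        return self.centers.shape[0]


def _grid_centers(lo, hi, step):
    n = max(int(round((hi - lo) / step)), 1)
    return lo + (np.arange(n) + 0.5) * step


def build_dual_mesh(
    roi_box,
    volume_bounds=DEFAULT_VOLUME_BOUNDS,
    fine_voxel=FINE_VOXEL,
    coarse_voxel=COARSE_VOXEL,
) -> DualMesh:
    """Tile the imaging volume with fine voxels in the ROI, coarse outside.

    ``roi_box`` is ((xmin, xmax), (ymin, ymax), (zmin, zmax)) around the
    ultrasound-indicated lesion; it is snapped *outward* to the coarse
    grid so the two voxel sets tile the volume exactly.  Fine voxel edges
    must divide the coarse ones (defaults do).
    """
    vb = np.asarray(volume_bounds, dtype=float)
    rb = np.asarray(roi_box, dtype=float)
    if np.any(rb[:, 0] >= rb[:, 1]):
        raise ValueError("ROI box must have positive extent on every axis")
    if np.any(rb[:, 0] < vb[:, 0] - 1e-9) or np.any(rb[:, 1] > vb[:, 1] + 1e-9):
        raise ValueError("ROI box must lie inside the imaging volume")
    cw = np.asarray(coarse_voxel, dtype=float)
    # snap ROI outward onto the coarse lattice anchored at the volume origin
    lo = vb[:, 0] + np.floor((rb[:, 0] - vb[:, 0]) / cw) * cw
    hi = vb[:, 0] + np.ceil((rb[:, 1] - vb[:, 0]) / cw) * cw
    hi = np.minimum(hi, vb[:, 1])
    lo = np.maximum(lo, vb[:, 0])
    snapped = tuple((lo[i], hi[i]) for i in range(3))

    fx, fy, fz = (
        _grid_centers(lo[i], hi[i], fine_voxel[i]) for i in range(3)
    )
    FX, FY, FZ = np.meshgrid(fx, fy, fz, indexing="ij")
    fine_centers = np.column_stack([FX.ravel(), FY.ravel(), FZ.ravel()])

    cx, cy, cz = (
        _grid_centers(vb[i, 0], vb[i, 1], cw[i]) for i in range(3)
    )
    CX, CY, CZ = np.meshgrid(cx, cy, cz, indexing="ij")
    coarse_centers = np.column_stack([CX.ravel(), CY.ravel(), CZ.ravel()])
    in_roi = np.all(
        (coarse_centers >= lo + 1e-9) & (coarse_centers <= hi - 1e-9), axis=1
    )
    coarse_centers = coarse_centers[~in_roi]

    centers = np.vstack([fine_centers, coarse_centers])
    sizes = np.vstack(
        [
            np.tile(np.asarray(fine_voxel, float), (fine_centers.shape[0], 1)),
            np.tile(cw, (coarse_centers.shape[0], 1)),
        ]
    )
    is_fine = np.zeros(centers.shape[0], dtype=bool)
    is_fine[: fine_centers.shape[0]] = True
    return DualMesh(
        centers=centers,
        sizes=sizes,
        is_fine=is_fine,
        bounds=tuple(map(tuple, vb)),
        roi_box=snapped,
    )


def roi_from_target(center, radius, volume_bounds=DEFAULT_VOLUME_BOUNDS, margin=0.5):
    """ROI box around a known lesion (the synthetic stand-in for US guidance)."""
    vb = np.asarray(volume_bounds, float)
    c = np.asarray(center, float)
    lo = np.maximum(c - radius - margin, vb[:, 0])
    hi = np.minimum(c + radius + margin, vb[:, 1])
    hi[2] = max(hi[2], lo[2] + 1e-6)
    return tuple((lo[i], hi[i]) for i in range(3))


@dataclass
class SensitivityMatrix:
    """Born weight matrix W (pairs x voxels) for the normalized perturbation."""

    W: np.ndarray  # complex
    mesh: DualMesh = field(repr=False)
    background: OpticalProperties = None


def assemble_sensitivity(
    mesh: DualMesh, geometry: ProbeGeometry, background: OpticalProperties
) -> SensitivityMatrix:
    """Assemble W with the simulation forward kernel (shared by construction):

        W[i, j] = -g(s_i, r_j) * g(r_j, d_i) * V_j / U0_i

    with ``g`` the extrapolated-boundary Green's function carrying the
    1/(4 pi D) fluence normalization (the g*g/g quotient absorbs the 1/D
    of the Born integral), so that ``W @ dmua`` is exactly the normalized
    Born perturbation of the voxelized absorption change ``dmua``.
    """
    params = ForwardModelParams.from_properties(background, geometry.omega)
    ps, pd = geometry.pair_positions()
    src = ps.copy()
    src[:, 2] = params.z0
    U0 = green_function(src, pd, params)
    c = mesh.centers
    g_sv = green_function(src[:, None, :], c[None, :, :], params)
    g_vd = green_function(c[None, :, :], pd[:, None, :], params)
    W = -(g_sv * g_vd) * mesh.volumes[None, :] / U0[:, None]
    if not np.all(np.isfinite(W)):
        raise FloatingPointError("non-finite sensitivity entries")
    return SensitivityMatrix(W=W, mesh=mesh, background=background)


@dataclass
class ReconResult:
    """Reconstructed absorption change and bookkeeping."""

    delta_mua: np.ndarray  # (n_voxels,) cm^-1, unconstrained sign
    mesh: DualMesh = field(repr=False, default=None)
    background_mua: float = 0.0
    regularization_lambda: float = 0.0
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True

    @property
    def mua_map(self) -> np.ndarray:
        return self.background_mua + self.delta_mua

    @property
    def max_mua(self) -> float:
        """Maximum reconstructed mua over the fine (lesion ROI) voxels."""
        fine = self.mua_map[self.mesh.is_fine]
        return float(fine.max()) if fine.size else float(self.mua_map.max())


#: Default regularization factor: lambda = LAMBDA_FACTOR * sigma_max of the
#: (depth-compensated) stacked sensitivity operator.
LAMBDA_FACTOR = 0.02
#: Default depth-compensation exponent: voxel j is penalized by its column
#: norm to this power, counteracting the strong near-surface sensitivity
#: bias of reflection-geometry probes.  0 disables compensation (plain
#: Tikhonov on the raw operator).
DEPTH_COMPENSATION = 0.5


def default_lambda(W: np.ndarray, factor: float = LAMBDA_FACTOR) -> float:
    """Regularization weight proportional to the top singular value of W."""
    A = np.vstack([W.real, W.imag])
    smax = np.linalg.norm(A, 2)
    return factor * smax


def reconstruct(
    pert: Perturbation,
    sensitivity: SensitivityMatrix,
    lam: float | None = None,
    depth_compensation: float = DEPTH_COMPENSATION,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ReconResult:
    """Tikhonov-regularized conjugate-gradient solve of the Born system.

    Real and imaginary parts are stacked into one real least-squares
    problem.  With ``depth_compensation`` p > 0 the penalty is weighted by
    the voxel sensitivity, ``min ||A x - b||^2 + lam^2 ||S x||^2`` with
    ``S = diag(||a_j||^p)``: without it, the minimum-norm solution of a
    reflection probe concentrates at the high-sensitivity voxels just
    beneath the optodes instead of at the lesion.  Substituting y = S x
    reduces the problem to plain Tikhonov on the column-weighted operator,
    whose normal equations ``(A'^T A' + lam^2 I) y = A'^T b`` are solved
    by conjugate gradient from a zero start.  ``lam=None`` selects
    ``0.02 * sigma_max`` of the weighted operator.
    """
    W = sensitivity.W
    if pert.values.size != W.shape[0]:
        raise ValueError("perturbation length does not match sensitivity rows")
    A = np.vstack([W.real, W.imag])
    b = np.concatenate([pert.values.real, pert.values.imag])
    if depth_compensation > 0:
        colnorm = np.linalg.norm(A, axis=0)
        colnorm[colnorm == 0] = 1.0
        S = colnorm**depth_compensation
    else:
        S = np.ones(A.shape[1])
    A = A / S
    if lam is None:
        lam = LAMBDA_FACTOR * np.linalg.norm(A, 2)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    rhs = A.T @ b
    n = A.shape[1]

    def matvec(y):
        return A.T @ (A @ y) + lam**2 * y

    it_count = [0]

    def cb(_):
        it_count[0] += 1

    op = LinearOperator((n, n), matvec=matvec, dtype=float)
    y, info = cg(op, rhs, rtol=tol, atol=0.0, maxiter=max_iter, callback=cb)
    residual = float(np.linalg.norm(matvec(y) - rhs) / max(np.linalg.norm(rhs), 1e-300))
    bg = sensitivity.background.mua if sensitivity.background is not None else 0.0
    return ReconResult(
        delta_mua=y / S,
        mesh=sensitivity.mesh,
        background_mua=bg,
        regularization_lambda=float(lam),
        iterations=it_count[0],
        residual=residual,
        converged=(info == 0),
    )


@dataclass
class LayeredMap:
    """Voxel map rasterized onto a uniform (nz, nx, ny) grid of depth layers."""

    values: np.ndarray  # (nz, nx, ny)
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray


def rasterize(
    values: np.ndarray,
    mesh: DualMesh,
    step=FINE_VOXEL,
) -> LayeredMap:
    """Resample a per-voxel map onto a uniform grid (voxel-membership lookup)."""
    vb = np.asarray(mesh.bounds, float)
    gx = _grid_centers(vb[0, 0], vb[0, 1], step[0])
    gy = _grid_centers(vb[1, 0], vb[1, 1], step[1])
    gz = _grid_centers(vb[2, 0], vb[2, 1], step[2])
    out = np.zeros((len(gz), len(gx), len(gy)))
    lo = mesh.centers - mesh.sizes / 2
    hi = mesh.centers + mesh.sizes / 2
    for v in range(mesh.n_voxels):
        xi = np.where((gx > lo[v, 0]) & (gx < hi[v, 0]))[0]
        yi = np.where((gy > lo[v, 1]) & (gy < hi[v, 1]))[0]
        zi = np.where((gz > lo[v, 2]) & (gz < hi[v, 2]))[0]
        out[np.ix_(zi, xi, yi)] = values[v]
    return LayeredMap(values=out, x=gx, y=gy, z=gz)


def compute_thb(mua_maps: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix absorption maps at the four wavelengths into hemoglobin, in uM.

    ``mua_maps`` maps wavelength (nm) -> mua array (any common shape).
    Per voxel, solves the nonnegative least-squares system

        mua(lambda) = ln(10) * [eps_HbO2(lambda) c_HbO2 + eps_Hb(lambda) c_Hb] * 1e-6

    with concentrations in micromolar.  Returns (tHb, HbO2, Hb).
    """
    wls = sorted(EXTINCTION)
    missing = [w for w in wls if w not in {float(k) for k in mua_maps}]
    if missing:
        raise ValueError(f"missing wavelengths for tHb unmixing: {missing}")
    maps = np.stack([np.asarray(mua_maps[w], float) for w in wls])
    E = np.array([EXTINCTION[w] for w in wls]) * np.log(10.0) * 1e-6
    flat = maps.reshape(len(wls), -1)
    conc = np.zeros((2, flat.shape[1]))
    for i in range(flat.shape[1]):
        conc[:, i], _ = nnls(E, flat[:, i])
    shape = maps.shape[1:]
    hbo2, hb = conc[0].reshape(shape), conc[1].reshape(shape)
    return hbo2 + hb, hbo2, hb
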