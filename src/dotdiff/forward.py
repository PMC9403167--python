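"""Analytic frequency-domain diffusion forward model.

Semi-infinite homogeneous medium with an extrapolated boundary: the
photon-density wave of a point source at depth z0 below the surface is
the free-space Green's function plus a negative image source mirrored
about the extrapolated plane z = -zb.  Absorbing inclusions (lesion,
chest wall, background heterogeneity) enter through a first-order Born
sum, which is also the kernel of the reconstruction sensitivity matrix,
so simulation and inversion share one forward operator by construction.

Sign convention: the complex wavenumber satisfies
``k**2 = (mua - i*omega/c) / D`` with ``Re(k) > 0``, so ``Im(k) < 0``
and the unwrapped phase of ``exp(-k*r)/r`` increases with distance.
"""

from __future__ import annotations

import numpy as np

from .geometry import (
    FDMeasurement,
    ForwardModelParams,
    OpticalProperties,
    ProbeGeometry,
)

_SINGULARITY_EPS = 1e-9


def _image_point(p: np.ndarray, zb: float) -> np.ndarray:
    """Mirror a point about the extrapolated boundary plane z = -zb."""
    img = np.array(p, dtype=float, copy=True)
    img[..., 2] = -(img[..., 2] + 2.0 * zb)
    return img


def green_function(
    src_points: np.ndarray,
    field_points: np.ndarray,
    params: ForwardModelParams,
) -> np.ndarray:
    """Extrapolated-boundary Green's function between interior points.

    Broadcasts over leading dimensions of ``src_points`` / ``field_points``
    (last axis is xyz).  Units: cm^-1 per unit source strength divided by D
    -- i.e. the fluence of a unit point source is ``green / (4*pi*D)``
    folded in here directly:

        G(r, r') = [exp(-k d1)/d1 - exp(-k d2)/d2] / (4 pi D)

    with d1 the direct distance and d2 the distance to the image source.
    """
    src = np.asarray(src_points, dtype=float)
    fp = np.asarray(field_points, dtype=float)
    d1 = np.linalg.norm(fp - src, axis=-1)
    d2 = np.linalg.norm(fp - _image_point(src, params.zb), axis=-1)
    if np.any(d1 < _SINGULARITY_EPS) or np.any(d2 < _SINGULARITY_EPS):
        raise ValueError("field point coincides with a real or image source")
    k = params.k
    return (np.exp(-k * d1) / d1 - np.exp(-k * d2) / d2) / (4.0 * np.pi * params.D)


def semi_infinite_green(
    source: np.ndarray,
    field_point: np.ndarray,
    props: OpticalProperties,
    omega: float,
) -> complex | np.ndarray:
    """Photon-density wave at ``field_point`` for a source fiber at ``source``.

    A source on the surface (z=0) is replaced by an equivalent isotropic
    source buried at depth z0 = 1/musp; a buried source (z>0) is used
    as-is.  Reciprocal in its two point arguments for buried points.

    Parameters
    ----------
    source, field_point : (..., 3) arrays, cm.  Field points must have z >= 0.
    props : background optical properties.
    omega : angular modulation frequency, rad/s (0 gives the DC limit,
        a purely real positive fluence).
    """
    src = np.array(np.asarray(source, dtype=float), copy=True)
    fp = np.asarray(field_point, dtype=float)
    if np.any(fp[..., 2] < 0):
        raise ValueError("field points must lie in the medium (z >= 0)")
    params = ForwardModelParams.from_properties(props, omega)
    surface = src[..., 2] == 0.0
    src[..., 2] = np.where(surface, params.z0, src[..., 2])
    out = green_function(src, fp, params)
    if out.ndim == 0:
        return complex(out)
    return out


def simulate_homogeneous(
    geometry: ProbeGeometry,
    props: OpticalProperties,
    wavelength: float | None = None,
) -> FDMeasurement:
    """Reflectance of the homogeneous background at every source-detector pair."""
    wavelength = geometry.wavelengths[0] if wavelength is None else wavelength
    ps, pd = geometry.pair_positions()
    U = semi_infinite_green(ps, pd, props, geometry.omega)
    return FDMeasurement(U=U, rho=geometry.rho(), wavelength=wavelength, geometry=geometry)


def born_perturbation(
    geometry: ProbeGeometry,
    props: OpticalProperties,
    voxel_centers: np.ndarray,
    voxel_volumes: np.ndarray,
    delta_mua: np.ndarray,
    U0: np.ndarray | None = None,
    chunk: int = 4096,
) -> np.ndarray:
    """Normalized first-order Born perturbation of absorbing voxels.

    Returns the complex vector ``(U_pert - U0) / U0`` per pair:

        pert_i = - sum_j g(s_i, r_j) g(r_j, d_i) dmua_j V_j / U0_i

    where ``g`` is :func:`green_function` (which carries the 1/(4 pi D)
    fluence normalization, so the product of two g factors over one g in
    the denominator absorbs the 1/D of the Born integral exactly).  The
    same kernel (without the dmua factor) is the sensitivity matrix of the
    linearized inverse problem; see
    :func:`dotdiff.reconstruction.assemble_sensitivity`.
    """
    centers = np.atleast_2d(np.asarray(voxel_centers, dtype=float))
    vols = np.broadcast_to(np.asarray(voxel_volumes, dtype=float), (centers.shape[0],))
    dmua = np.broadcast_to(np.asarray(delta_mua, dtype=float), (centers.shape[0],))
    if centers.size and np.any(centers[:, 2] <= 0):
        raise ValueError("inclusion voxels must lie strictly inside the medium (z > 0)")
    params = ForwardModelParams.from_properties(props, geometry.omega)
    ps, pd = geometry.pair_positions()
    src = ps.copy()
    src[:, 2] = params.z0  # equivalent buried sources
    if U0 is None:
        U0 = green_function(src, pd, params)
    pert = np.zeros(geometry.n_pairs, dtype=complex)
    for start in range(0, centers.shape[0], chunk):
        c = centers[start : start + chunk]
        w = (dmua * vols)[start : start + chunk]
        g_sv = green_function(src[:, None, :], c[None, :, :], params)  # (pairs, nv)
        g_vd = green_function(c[None, :, :], pd[:, None, :], params)
        pert += (g_sv * g_vd) @ w
    return -pert / U0


def fit_background(
    meas: FDMeasurement,
    geometry: ProbeGeometry,
    initial: tuple[float, float] = (0.05, 6.0),
    bounds: tuple = ((0.001, 0.5), (2.0, 15.0)),  # (mua, musp) (lo, hi) pairs
) -> OpticalProperties:
    """Estimate bulk (mua, musp) of the medium from one reflectance measurement.

    Fits the semi-infinite homogeneous model to the *shapes* of
    ``log(A*rho^2)`` and unwrapped phase versus separation (per-channel
    offsets are removed, so unknown coupling coefficients drop out) --
    the standard way reference measurements supply the background optical
    properties for difference imaging.  Structures in the medium (chest
    wall, heterogeneity, a lesion) bias the fit toward effective bulk
    values; that bias is part of the measurement physics this function
    deliberately reproduces.
    """
    from scipy.optimize import least_squares

    log_amp = np.log(meas.amplitude * meas.rho**2)
    phase = meas.phase

    def residuals(x):
        props = OpticalProperties(mua=x[0], musp=x[1])
        m = simulate_homogeneous(geometry, props)
        la = np.log(m.amplitude * m.rho**2)
        ph = m.phase
        return np.concatenate(
            [
                (log_amp - log_amp.mean()) - (la - la.mean()),
                (phase - phase.mean()) - (ph - ph.mean()),
            ]
        )

    lo, hi = zip(*bounds)
    sol = least_squares(residuals, list(initial), bounds=(lo, hi))
    return OpticalProperties(mua=float(sol.x[0]), musp=float(sol.x[1]))


def simulate_with_inclusions(
    geometry: ProbeGeometry,
    background: OpticalProperties,
    inclusions: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    wavelength: float | None = None,
    composition: str = "born",
) -> FDMeasurement:
    """Reflectance with absorbing inclusions built on the Born kernel.

    Parameters
    ----------
    inclusions : list of (voxel_centers (n,3) cm, voxel_volumes (n,) cm^3,
        delta_mua (n,) cm^-1) triples.  delta_mua is the excess absorption
        over the background; scattering contrast is not modelled.
    composition : "born" or "rytov".
        "born" composes linearly, ``U = U0 * (1 + sum_k p_k)`` -- exactly the
        operator the sensitivity matrix linearizes, so forward and inversion
        share one kernel to machine precision.  "rytov" composes
        exponentially, ``U = U0 * exp(sum_k p_k)``, which agrees with Born to
        first order but stays physical (positive amplitude, relative
        perturbation never below -1) at the high lesion/chest-wall contrasts
        of the scene corpus; structures shared by two measurements cancel
        exactly in their ratio.  Scene simulation uses "rytov".
    """
    if composition not in ("born", "rytov"):
        raise ValueError(f"unknown composition {composition!r}")
    meas0 = simulate_homogeneous(geometry, background, wavelength)
    total = np.zeros(geometry.n_pairs, dtype=complex)
    for centers, vols, dmua in inclusions:
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        if centers.shape[0] == 0:
            continue
        total += born_perturbation(geometry, background, centers, vols, dmua, U0=meas0.U)
    factor = (1.0 + total) if composition == "born" else np.exp(total)
    return meas0.with_U(meas0.U * factor)
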