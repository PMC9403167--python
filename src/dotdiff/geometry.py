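"""Probe geometry and frequency-domain measurement containers.

Conventions used throughout the package: lengths in cm, optical
coefficients in cm^-1, phase in radians, modulation frequency in Hz.
The tissue occupies the half-space z > 0 (depth positive); sources and
detectors sit on the surface plane z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Speed of light in vacuum, cm/s.
C_VACUUM = 2.99792458e10

#: Laser-diode wavelengths of the imager, nm.
DEFAULT_WAVELENGTHS = (730.0, 785.0, 808.0, 830.0)

#: Modulation frequency of the frequency-domain system, Hz.
DEFAULT_MODULATION_HZ = 140e6

#: Imaging volume under the probe, cm: ((xmin, xmax), (ymin, ymax), (zmin, zmax)).
DEFAULT_VOLUME_BOUNDS = ((-4.0, 4.0), (-4.0, 4.0), (0.0, 4.0))


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous optical properties of a turbid medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient, cm^-1.
    musp : float
        Reduced scattering coefficient, cm^-1.  Diffusion theory requires
        ``musp >> mua``.
    refractive_index : float
        Interior refractive index (tissue/Intralipid-like by default).
    """

    mua: float
    musp: float
    refractive_index: float = 1.333

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError(
                f"optical properties must be positive (mua={self.mua}, musp={self.musp})"
            )
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class ForwardModelParams:
    """Derived quantities of the diffusion forward model.

    Attributes
    ----------
    D : float
        Diffusion coefficient, cm: ``D = 1 / (3 (mua + musp))``.
    k : complex
        Complex wavenumber, cm^-1, with ``k**2 = (mua - i w / c) / D``
        and ``Re(k) > 0``.  With this sign convention the phase of the
        fluence *increases* with propagation distance.
    z0 : float
        Effective isotropic source depth, cm: ``1 / musp``.
    zb : float
        Extrapolated-boundary distance, cm.
    reff : float
        Effective Fresnel reflection coefficient of the boundary.
    """

    D: float
    k: complex
    z0: float
    zb: float
    reff: float

    @classmethod
    def from_properties(
        cls, props: OpticalProperties, omega: float
    ) -> "ForwardModelParams":
        """Derive diffusion parameters at angular modulation frequency ``omega`` (rad/s)."""
        D = 1.0 / (3.0 * (props.mua + props.musp))
        c_medium = C_VACUUM / props.refractive_index
        k = np.sqrt((props.mua - 1j * omega / c_medium) / D)
        if k.real < 0:
            k = -k
        n = props.refractive_index
        # Groenhuis-style polynomial fit for the effective reflection coefficient.
        reff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        z0 = 1.0 / props.musp
        zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
        return cls(D=D, k=complex(k), z0=z0, zb=zb, reff=reff)


@dataclass(frozen=True)
class ProbeGeometry:
    """Hand-held reflectance probe: sources and detectors on the z=0 plane.

    The default layout places 9 source fibers on one side and 14
    photomultiplier detectors on the other side of a central gap that
    holds the ultrasound transducer, giving 126 source-detector pairs.
    Each pair contributes two numbers (log amplitude and phase, or real
    and imaginary part), matching the 252-wide network interface.
    """

    source_positions: np.ndarray  # (n_src, 3)
    detector_positions: np.ndarray  # (n_det, 3)
    modulation_frequency: float = DEFAULT_MODULATION_HZ
    wavelengths: tuple = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source_positions, dtype=float))
        det = np.atleast_2d(np.asarray(self.detector_positions, dtype=float))
        if src.shape[1] != 3 or det.shape[1] != 3:
            raise ValueError("positions must be (n, 3) arrays")
        if not (np.allclose(src[:, 2], 0.0) and np.allclose(det[:, 2], 0.0)):
            raise ValueError("sources and detectors must lie on the z=0 surface")
        object.__setattr__(self, "source_positions", src)
        object.__setattr__(self, "detector_positions", det)

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.detector_positions.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_sources * self.n_detectors

    @property
    def omega(self) -> float:
        """Angular modulation frequency, rad/s."""
        return 2.0 * np.pi * self.modulation_frequency

    def pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Source and detector index per pair, sorted by source then detector."""
        s, d = np.meshgrid(
            np.arange(self.n_sources), np.arange(self.n_detectors), indexing="ij"
        )
        return s.ravel(), d.ravel()

    def pair_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_pairs, 3) source and detector coordinates, pair-ordered."""
        s, d = self.pair_index()
        return self.source_positions[s], self.detector_positions[d]

    def rho(self) -> np.ndarray:
        """Source-detector separation per pair, cm."""
        ps, pd = self.pair_positions()
        return np.linalg.norm(ps - pd, axis=1)


def default_probe(
    modulation_frequency: float = DEFAULT_MODULATION_HZ,
    wavelengths: tuple = DEFAULT_WAVELENGTHS,
) -> ProbeGeometry:
    """Default 9-source / 14-detector probe (~9 cm face, central US gap).

    Sources: 3x3 grid, x in [-3.3, -1.5] cm; detectors: 2x7 grid,
    x in [1.5, 3.9] cm.  The central band |x| < 1.5 cm is left free for
    the ultrasound transducer.  Minimum source-detector separation is
    3.0 cm, keeping every pair in the diffusive regime.
    """
    sx = np.array([-3.3, -2.4, -1.5])
    sy = np.array([-1.0, 0.0, 1.0])
    sources = np.array([[x, y, 0.0] for x in sx for y in sy])
    dx = np.array([1.5, 1.9, 2.3, 2.7, 3.1, 3.5, 3.9])
    dy = np.array([-0.8, 0.8])
    detectors = np.array([[x, y, 0.0] for x in dx for y in dy])
    return ProbeGeometry(
        source_positions=sources,
        detector_positions=detectors,
        modulation_frequency=modulation_frequency,
        wavelengths=wavelengths,
    )


@dataclass
class FDMeasurement:
    """Complex diffuse reflectance per source-detector pair at one wavelength.

    ``U`` is the complex photon-density wave at the detector; ``amplitude``
    and ``phase`` are its polar form (phase unwrapped along increasing
    separation within each source, see :func:`unwrap_phase_by_source`).
    """

    U: np.ndarray  # complex, (n_pairs,)
    rho: np.ndarray  # cm, (n_pairs,)
    wavelength: float  # nm
    geometry: ProbeGeometry = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=complex)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.U.shape != self.rho.shape:
            raise ValueError("U and rho must have matching shapes")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.U)

    @property
    def phase(self) -> np.ndarray:
        """Unwrapped phase, radians (per-source unwrap along increasing rho)."""
        if self.geometry is not None:
            return unwrap_phase_by_source(np.angle(self.U), self.geometry, self.rho)
        return np.unwrap(np.angle(self.U))

    def with_U(self, U: np.ndarray) -> "FDMeasurement":
        return FDMeasurement(U=U, rho=self.rho, wavelength=self.wavelength, geometry=self.geometry)


def unwrap_phase_by_source(
    phase: np.ndarray, geometry: ProbeGeometry, rho: np.ndarray
) -> np.ndarray:
    """Unwrap raw phase pair-wise, per source, along increasing separation.

    Within each source's 14 detector readings the phase is sorted by rho,
    unwrapped by nearest multiple of 2*pi, and restored to pair order.
    """
    out = np.array(phase, dtype=float)
    n_det = geometry.n_detectors
    for s in range(geometry.n_sources):
        sl = slice(s * n_det, (s + 1) * n_det)
        order = np.argsort(rho[sl], kind="stable")
        ph = out[sl][order]
        out_sl = np.empty_like(ph)
        out_sl[order] = np.unwrap(ph)
        out[sl] = out_sl
    return out
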