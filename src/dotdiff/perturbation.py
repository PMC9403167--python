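"""Normalized perturbation for difference imaging, and network I/O layout.

The normalized perturbation is the relative complex change of the
lesion-side reflectance Ul against a reference Ur measured on lesion-free
tissue with (ideally) the same background:

    pert = (Ul - Ur) / Ur
         = (Al/Ar * cos(phi_l - phi_r) - 1) + j * Al/Ar * sin(phi_l - phi_r)

For a pure absorber on a matched background, Al < Ar and the phase
difference stays below 90 degrees, so the real part lies in [-1, 0].
Because any multiplicative coupling coefficient shared by Ul and Ur
cancels in the ratio, difference imaging is insensitive to source power
and detector gain -- the property the network is trained to preserve.

Network layout (fixed, versioned with model artifacts):
  inputs  (252,): 126 values of log(A * rho^2) offset to a common maximum
                  of 0, then 126 unwrapped phases offset to a common
                  minimum of 0; pairs sorted by source then detector.
  outputs (252,): 126 real parts then 126 imaginary parts of pert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FDMeasurement

#: Common maximum of log(A*rho^2) after offsetting, shared by all datasets.
COMMON_MAX_LOGAMP = 0.0
#: Common minimum of the unwrapped phase after offsetting.
COMMON_MIN_PHASE = 0.0

PROVENANCES = ("measured_matched", "measured_mismatched", "ann_predicted")


@dataclass
class Perturbation:
    """Complex normalized perturbation, one entry per source-detector pair."""

    values: np.ndarray
    wavelength: float
    provenance: str = "measured_matched"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def real(self) -> np.ndarray:
        return self.values.real

    @property
    def imag(self) -> np.ndarray:
        return self.values.imag

    def to_vector(self) -> np.ndarray:
        """Stacked (2*n_pairs,) real vector: all real parts then all imaginary."""
        return np.concatenate([self.values.real, self.values.imag])

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, wavelength: float, provenance: str
    ) -> "Perturbation":
        vec = np.asarray(vec, dtype=float)
        n = vec.size // 2
        return cls(vec[:n] + 1j * vec[n:], wavelength, provenance)


@dataclass
class NormalizedInput:
    """Offset-normalized measurement ready for the network."""

    log_amp: np.ndarray
    phase: np.ndarray
    amp_offset: float
    phase_offset: float

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.log_amp, self.phase])

    def denormalize(self) -> tuple[np.ndarray, np.ndarray]:
        """Undo the additive offsets (identity round trip)."""
        return self.log_amp + self.amp_offset, self.phase + self.phase_offset


def compute_perturbation(Ul: FDMeasurement, Ur: FDMeasurement) -> Perturbation:
    """Normalized perturbation of a lesion-side measurement against a reference.

    Both measurements must share geometry and wavelength. Raises on a zero
    reference amplitude.
    """
    if Ul.U.shape != Ur.U.shape or not np.allclose(Ul.rho, Ur.rho):
        raise ValueError("lesion and reference measurements are not pair-matched")
    if Ul.wavelength != Ur.wavelength:
        raise ValueError("wavelength mismatch between lesion and reference")
    if np.any(Ur.amplitude == 0):
        raise ZeroDivisionError("reference amplitude is zero at some pair")
    ratio = Ul.amplitude / Ur.amplitude
    dphi = Ul.phase - Ur.phase
    values = ratio * np.cos(dphi) - 1.0 + 1j * ratio * np.sin(dphi)
    return Perturbation(values=values, wavelength=Ul.wavelength, provenance="measured_matched")


def rytov_linearize(pert: Perturbation, floor: float = 1e-6) -> Perturbation:
    """Rytov-linearized data for reconstruction: ``log(1 + pert)``.

    ``1 + pert = Ul/Ur``, so the transform returns ``log(Al/Ar) +
    j*(phi_l - phi_r)`` -- the log-amplitude/phase form of the
    perturbation.  At the lesion and chest-wall contrasts of breast
    imaging the measured perturbation saturates (its magnitude grows
    sublinearly in the absorption change), and fitting the saturated
    values with a linear Born model mislocates the recovered absorber;
    the log transform removes the saturation while leaving the
    small-perturbation limit unchanged (log(1+p) -> p).  The amplitude
    ratio is floored at ``floor`` and the phase difference clipped to
    +/- pi/2 -- the admissible range of the difference-imaging model
    (both are no-ops for physically measured data, and guard against
    network predictions that stray past pert = -1, where the complex log
    would otherwise flip branch and destabilize the inversion).
    """
    z = 1.0 + pert.values
    mag = np.maximum(np.abs(z), floor)
    ang = np.clip(np.angle(z), -np.pi / 2, np.pi / 2)
    return Perturbation(
        values=np.log(mag) + 1j * ang,
        wavelength=pert.wavelength,
        provenance=pert.provenance,
    )


def normalize_for_network(
    measurement: FDMeasurement,
    common_max_logamp: float = COMMON_MAX_LOGAMP,
    common_min_phase: float = COMMON_MIN_PHASE,
) -> NormalizedInput:
    """Offset log(A*rho^2) and unwrapped phase to dataset-independent anchors.

    Only additive offsets are applied, so the *shape* of both channels is
    preserved; a global gain on the amplitudes (coupling coefficient,
    source power) is absorbed entirely into the amplitude offset.
    """
    amp = measurement.amplitude
    if np.any(amp <= 0):
        raise ValueError("amplitudes must be positive")
    log_amp = np.log(amp * measurement.rho**2)
    phase = measurement.phase
    amp_offset = log_amp.max() - common_max_logamp
    phase_offset = phase.min() - common_min_phase
    return NormalizedInput(
        log_amp=log_amp - amp_offset,
        phase=phase - phase_offset,
        amp_offset=amp_offset,
        phase_offset=phase_offset,
    )
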