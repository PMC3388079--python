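"""Confocal observation-volume calibration.

For lateral diffusion through a Gaussian observation volume the diffusion
time and diffusion coefficient are linked by

    tau_D = omega^2 / (4 D)

where omega is the lateral radius of the observation volume. Measuring
tau_D for a reference dye of known D (classically rhodamine 6G) therefore
calibrates omega, after which diffusion times of arbitrary species convert
to diffusion coefficients and vice versa.

Public units: D in cm^2/s, tau_D in ms, omega in nm. Conversions go
through SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .models import ConfocalGeometry

__all__ = [
    "ReferenceDye",
    "REFERENCE_DYES",
    "beam_radius_from_reference",
    "tau_d_from_d",
    "d_from_tau_d",
]

_CM2_TO_NM2 = 1e14  # (1 cm)^2 in nm^2
_MS_TO_S = 1e-3


@dataclass(frozen=True)
class ReferenceDye:
    """A calibration standard: literature diffusion coefficient plus the
    diffusion time measured on the instrument being calibrated."""

    name: str
    d: float  # cm^2/s, literature value
    tau_d: float  # ms, measured on the setup
    source: str = ""

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise DomainError(f"diffusion coefficient must be > 0, got {self.d}")
        if not self.tau_d > 0:
            raise DomainError(f"tau_d must be > 0, got {self.tau_d}")


#: Built-in reference dyes (literature D at ~25 degC). The measured tau_d
#: is instrument-specific; these entries carry the value from the halted
#: elongation-complex FCS setup they describe and should be overridden for
#: any other instrument.
REFERENCE_DYES: dict[str, ReferenceDye] = {
    "rhodamine6g": ReferenceDye(
        name="rhodamine6g",
        d=4.14e-6,
        tau_d=0.38,
        source="two-focus FCS literature value for R6G in water",
    ),
}


def beam_radius_from_reference(ref: ReferenceDye) -> float:
    """Lateral observation-volume radius omega = sqrt(4 * D * tau_D), nm."""
    omega_nm2 = 4.0 * (ref.d * _CM2_TO_NM2) * (ref.tau_d * _MS_TO_S)
    return omega_nm2**0.5


def tau_d_from_d(d: float, geom: ConfocalGeometry) -> float:
    """Diffusion time tau_D = omega^2/(4 D) in ms, for D in cm^2/s."""
    if geom.omega is None:
        raise ConfigurationError("geometry has no omega; calibrate first")
    if not d > 0:
        raise DomainError(f"diffusion coefficient must be > 0, got {d}")
    return geom.omega**2 / (4.0 * d * _CM2_TO_NM2) / _MS_TO_S


def d_from_tau_d(tau_d: float, geom: ConfocalGeometry) -> float:
    """Diffusion coefficient D = omega^2/(4 tau_D) in cm^2/s, for tau_D in ms."""
    if geom.omega is None:
        raise ConfigurationError("geometry has no omega; calibrate first")
    if not tau_d > 0:
        raise DomainError(f"tau_d must be > 0, got {tau_d}")
    return geom.omega**2 / (4.0 * tau_d * _MS_TO_S) / _CM2_TO_NM2
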