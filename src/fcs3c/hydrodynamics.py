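"""Hydrodynamic diffusion-time predictions.

Globular proteins are modelled as hydrated spheres: the anhydrous volume
follows from the molecular mass and partial specific volume, hydration
adds bound water at ~1 cm^3/g, and the Stokes-Einstein relation
D = k_B T / (6 pi eta r) converts the hydrated radius to a diffusion
coefficient. The observation-volume calibration then yields the expected
diffusion time on a given instrument.

Short duplex DNA does not follow a simple sphere; its diffusion time is
scaled empirically from an anchor measurement via
tau_D ~ (bp)^b with a flexible-chain exponent b ~ 0.72.

The "non-interacting window" for a complex built from independently
measured components runs from the slowest component's tau_D (a complex
cannot diffuse faster than its largest part) up to the sum of the
component tau_D values (a conservative ceiling for a compact assembly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import tau_d_from_d
from .errors import DomainError
from .models import ConfocalGeometry

__all__ = [
    "HydroAssumptions",
    "protein_tau_d",
    "dna_tau_d_scaled",
    "noninteracting_window",
]

_KB = 1.380649e-23  # J/K
_NA = 6.02214076e23  # 1/mol
_WATER_SPECIFIC_VOLUME = 1.0  # cm^3/g


@dataclass(frozen=True)
class HydroAssumptions:
    """Physical constants behind the hydrated-sphere prediction.

    temperature : K (default 298.15, room temperature)
    viscosity : Pa*s (default 8.9e-4, water at 25 degC)
    partial_specific_volume : cm^3/g (default 0.73, typical protein)
    hydration : g bound water per g protein (default 0.3)
    dna_rise : nm per bp of B-form duplex (default 0.34)
    dna_scaling_exponent : empirical tau_D ~ bp^b exponent (default 0.72)
    """

    temperature: float = 298.15
    viscosity: float = 8.9e-4
    partial_specific_volume: float = 0.73
    hydration: float = 0.3
    dna_rise: float = 0.34
    dna_scaling_exponent: float = 0.72

    def __post_init__(self) -> None:
        for name in (
            "temperature",
            "viscosity",
            "partial_specific_volume",
            "dna_rise",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.hydration < 0:
            raise DomainError(f"hydration must be >= 0, got {self.hydration}")


def hydrated_radius_nm(mass_kda: float, assume: HydroAssumptions) -> float:
    """Radius of the equivalent hydrated sphere, nm."""
    if not mass_kda > 0:
        raise DomainError(f"mass must be > 0 kDa, got {mass_kda}")
    mass_g_per_mol = mass_kda * 1e3
    vol_cm3 = (
        mass_g_per_mol
        * (assume.partial_specific_volume + assume.hydration * _WATER_SPECIFIC_VOLUME)
        / _NA
    )
    r_cm = (3.0 * vol_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return r_cm * 1e7


def protein_diffusion_coefficient(mass_kda: float, assume: HydroAssumptions) -> float:
    """Stokes-Einstein D of a hydrated globular protein, cm^2/s."""
    r_m = hydrated_radius_nm(mass_kda, assume) * 1e-9
    d_m2_s = _KB * assume.temperature / (6.0 * np.pi * assume.viscosity * r_m)
    return d_m2_s * 1e4


def protein_tau_d(
    mass_kda: float,
    geom: ConfocalGeometry,
    assume: HydroAssumptions = HydroAssumptions(),
) -> float:
    """Expected diffusion time (ms) of a globular protein of given mass on
    the instrument described by ``geom``."""
    d = protein_diffusion_coefficient(mass_kda, assume)
    return tau_d_from_d(d, geom)


def dna_tau_d_scaled(
    bp: float,
    anchor_bp: float,
    anchor_tau_d: float,
    assume: HydroAssumptions = HydroAssumptions(),
) -> float:
    """Scale a measured duplex-DNA diffusion time to another length:
    tau_D(bp) = anchor_tau_D * (bp/anchor_bp)^b."""
    if not bp > 0 or not anchor_bp > 0:
        raise DomainError(f"DNA lengths must be > 0 bp, got {bp} and {anchor_bp}")
    if not anchor_tau_d > 0:
        raise DomainError(f"anchor tau_d must be > 0, got {anchor_tau_d}")
    return anchor_tau_d * (bp / anchor_bp) ** assume.dna_scaling_exponent


def noninteracting_window(component_tau_ds: Sequence[float]) -> tuple[float, float]:
    """Expected diffusion-time interval for a complex of non-interacting
    parts: [max of components, sum of components] in ms."""
    if len(component_tau_ds) == 0:
        raise DomainError("need at least one component diffusion time")
    arr = np.asarray(component_tau_ds, dtype=float)
    if not np.all(arr > 0):
        raise DomainError("component diffusion times must be > 0")
    return float(arr.max()), float(arr.sum())
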