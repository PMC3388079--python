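"""Analytic FCS autocorrelation models.

The normalized fluorescence autocorrelation function G(tau) of freely
diffusing fluorophores decays on the time scale of the translational
diffusion time tau_D and has amplitude G(0) = 1/N, where N is the mean
number of fluorescent molecules in the observation volume.

Three models are provided:

* single-species 2D:   G(tau) = (1/N) * (1 + tau/tau_D)^-1
  (appropriate for elongated confocal spots with w_z >> w_xy, where axial
  diffusion never decorrelates the signal within the lag range);
* single-species 3D:   the 2D form times (1 + tau/(A^2 tau_D))^-1/2,
  with structure parameter A = w_z/w_xy; the 3D model converges to the
  2D model as A -> infinity;
* two species of equal brightness:
  G(tau) = [N1*g1(tau) + N2*g2(tau)] / (N1 + N2)^2,
  where g_i is the single-species kernel without its 1/N prefactor. This
  amplitude weighting is the unique equal-brightness convention that
  collapses exactly to the single-species model when tau_D1 = tau_D2.

All lag times and diffusion times are in milliseconds. Triplet/photophysics
terms, flow and anomalous diffusion are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import ConfigurationError, DomainError

__all__ = [
    "ConfocalGeometry",
    "SpeciesParams",
    "CorrelationCurve",
    "default_lag_grid",
    "eval_single_2d",
    "eval_single_3d",
    "eval_two_species",
]

#: default lag grid for generated curves: log-spaced, 1e-3..1e4 ms, 200
#: points — spans a hardware correlator's range, from sub-ms dyes to slow
#: complexes.
DEFAULT_LAG_RANGE_MS = (1e-3, 1e4)
DEFAULT_LAG_POINTS = 200


def default_lag_grid(
    lo: float = DEFAULT_LAG_RANGE_MS[0],
    hi: float = DEFAULT_LAG_RANGE_MS[1],
    n: int = DEFAULT_LAG_POINTS,
) -> NDArray[np.float64]:
    """Logarithmically spaced lag grid in milliseconds."""
    if not (0 < lo < hi):
        raise DomainError(f"invalid lag range ({lo}, {hi}): need 0 < lo < hi")
    return np.logspace(np.log10(lo), np.log10(hi), int(n))


@dataclass(frozen=True)
class ConfocalGeometry:
    """Observation-volume geometry.

    Parameters
    ----------
    omega : float, optional
        Lateral (axial beam) radius w_xy in nm.
    structure_param : float, optional
        A = w_z/w_xy, the ratio of longitudinal to lateral radii.
        ``None`` selects the 2D approximation (the A -> infinity limit,
        valid for elongated confocal spots with w_z >> w_xy).
    """

    omega: float | None = None
    structure_param: float | None = None

    def __post_init__(self) -> None:
        if self.omega is not None and not self.omega > 0:
            raise DomainError(f"omega must be > 0, got {self.omega}")
        if self.structure_param is not None and not self.structure_param > 1:
            raise DomainError(
                f"structure_param A must be > 1, got {self.structure_param}"
            )

    @property
    def is_3d(self) -> bool:
        return self.structure_param is not None


@dataclass(frozen=True)
class SpeciesParams:
    """Mean occupancy N (molecules) and diffusion time tau_d (ms) of one
    diffusing species."""

    n: float
    tau_d: float

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise DomainError(f"N must be > 0, got {self.n}")
        if not self.tau_d > 0:
            raise DomainError(f"tau_d must be > 0, got {self.tau_d}")


@dataclass
class CorrelationCurve:
    """An autocorrelation curve: G(tau) sampled on a strictly increasing
    positive lag grid (ms), with optional per-lag standard deviations.

    ``meta`` is a free-form provenance record (source, seed, model, ...).
    """

    lags: NDArray[np.float64]
    values: NDArray[np.float64]
    sd: NDArray[np.float64] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.lags.size == 0:
            raise DomainError("lags must be a non-empty 1-D array")
        if self.values.shape != self.lags.shape:
            raise DomainError(
                f"values shape {self.values.shape} != lags shape {self.lags.shape}"
            )
        if not np.all(self.lags > 0):
            raise DomainError("lags must be strictly positive")
        if not np.all(np.diff(self.lags) > 0):
            raise DomainError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("values must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.lags.shape:
                raise DomainError("sd must have the same length as lags")
            if not np.all(self.sd >= 0):
                raise DomainError("sd must be nonnegative")

    def __len__(self) -> int:
        return self.lags.size


def _diffusion_kernel(
    lags: NDArray[np.float64], tau_d: float, structure_param: float | None
) -> NDArray[np.float64]:
    """Single-species diffusion kernel g(tau) without the 1/N prefactor."""
    g = 1.0 / (1.0 + lags / tau_d)
    if structure_param is not None:
        g = g / np.sqrt(1.0 + lags / (structure_param**2 * tau_d))
    return g


def eval_single_2d(lags: ArrayLike, params: SpeciesParams) -> CorrelationCurve:
    """Evaluate the single-species 2D model G = (1/N)(1 + tau/tau_D)^-1."""
    lags = np.asarray(lags, dtype=float)
    values = _diffusion_kernel(lags, params.tau_d, None) / params.n
    return CorrelationCurve(
        lags, values, meta={"model": "single_2d", "n": params.n, "tau_d": params.tau_d}
    )


def eval_single_3d(
    lags: ArrayLike, params: SpeciesParams, geom: ConfocalGeometry
) -> CorrelationCurve:
    """Evaluate the single-species 3D model; requires geom.structure_param."""
    if geom.structure_param is None:
        raise ConfigurationError(
            "3D model requires a structure parameter A = w_z/w_xy"
        )
    lags = np.asarray(lags, dtype=float)
    values = _diffusion_kernel(lags, params.tau_d, geom.structure_param) / params.n
    return CorrelationCurve(
        lags,
        values,
        meta={
            "model": "single_3d",
            "n": params.n,
            "tau_d": params.tau_d,
            "structure_param": geom.structure_param,
        },
    )


def eval_two_species(
    lags: ArrayLike,
    p1: SpeciesParams,
    p2: SpeciesParams,
    geom: ConfocalGeometry | None = None,
) -> CorrelationCurve:
    """Two equally bright species:
    G = [N1 g1 + N2 g2] / (N1 + N2)^2.

    The kernel (2D or 3D) follows ``geom``; ``None`` or a geometry without
    a structure parameter selects the 2D kernel. Reduces exactly to the
    single-species model when tau_d1 == tau_d2.
    """
    a = geom.structure_param if geom is not None else None
    lags = np.asarray(lags, dtype=float)
    n_tot = p1.n + p2.n
    values = (
        p1.n * _diffusion_kernel(lags, p1.tau_d, a)
        + p2.n * _diffusion_kernel(lags, p2.tau_d, a)
    ) / n_tot**2
    return CorrelationCurve(
        lags,
        values,
        meta={
            "model": "two_species",
            "n1": p1.n,
            "tau_d1": p1.tau_d,
            "n2": p2.n,
            "tau_d2": p2.tau_d,
            "structure_param": a,
        },
    )
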