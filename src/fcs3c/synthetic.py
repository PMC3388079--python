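"""Seeded synthetic-data generators.

Every analysis stage can be exercised on data with known ground truth:

* :func:`gen_curve` adds independent zero-mean Gaussian noise to an
  analytic autocorrelation curve, with a per-lag standard deviation that
  decays as a power of lag. This is a pragmatic stand-in for the
  statistics of a hardware correlator integrating a 10-s trace — it is
  NOT a photon-level simulation, and in particular neglects the
  correlations between neighbouring lag channels that real multiple-tau
  correlators produce.
* :func:`gen_band_table` builds a gel band table with the exact
  multiplicative structure the normalization algebra assumes:
  intensity = primer efficiency x ligation frequency x condition scale
  x lognormal noise, so the true interaction-frequency ratio is known.

Both generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .models import (
    ConfocalGeometry,
    CorrelationCurve,
    SpeciesParams,
    default_lag_grid,
    eval_single_2d,
    eval_single_3d,
    eval_two_species,
)

__all__ = ["CurveNoiseSpec", "gen_curve", "gen_band_table"]


@dataclass(frozen=True)
class CurveNoiseSpec:
    """Noise model for synthetic autocorrelation curves.

    sigma0 : noise SD at the first lag, as a fraction of G(0)
    lag_power : exponent of the power-law SD decay with lag
    seed : RNG seed
    """

    sigma0: float = 0.005
    lag_power: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise DomainError(f"sigma0 must be >= 0, got {self.sigma0}")


def gen_curve(
    truth: SpeciesParams | Sequence[SpeciesParams],
    geom: ConfocalGeometry | None = None,
    noise: CurveNoiseSpec = CurveNoiseSpec(),
    lag_grid: tuple[float, float, int] | np.ndarray | None = None,
) -> CorrelationCurve:
    """Generate a (possibly noisy) autocorrelation curve with known truth.

    ``truth`` is one SpeciesParams (single-species model; 3D when ``geom``
    has a structure parameter) or a pair (two-species model). The returned
    curve's ``sd`` holds the true per-lag noise SD and ``meta`` records
    the full generating recipe.
    """
    if lag_grid is None:
        lags = default_lag_grid()
    elif isinstance(lag_grid, tuple):
        lo, hi, n = lag_grid
        lags = default_lag_grid(lo, hi, n)
    else:
        lags = np.asarray(lag_grid, dtype=float)

    if isinstance(truth, SpeciesParams):
        if geom is not None and geom.is_3d:
            clean = eval_single_3d(lags, truth, geom)
        else:
            clean = eval_single_2d(lags, truth)
    else:
        species = list(truth)
        if len(species) != 2:
            raise DomainError(f"truth must be one or two species, got {len(species)}")
        clean = eval_two_species(lags, species[0], species[1], geom)

    g0 = clean.values[0]
    sd = noise.sigma0 * g0 * (lags / lags[0]) ** (-noise.lag_power)
    sd = np.maximum(sd, np.finfo(float).eps)
    if noise.sigma0 == 0:
        values = clean.values.copy()
        sd_out = np.zeros_like(sd)
    else:
        rng = np.random.default_rng(noise.seed)
        values = clean.values + rng.normal(0.0, sd)
        sd_out = sd
    meta = dict(clean.meta)
    meta.update(
        {
            "source": "synthetic",
            "sigma0": noise.sigma0,
            "lag_power": noise.lag_power,
            "seed": noise.seed,
        }
    )
    return CorrelationCurve(lags, values, sd=sd_out, meta=meta)


def gen_band_table(
    true_ratio: float,
    primer_efficiencies: Mapping[str, float] | None = None,
    condition_scales: Mapping[str, float] | None = None,
    noise_cv: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    masses: Sequence[float] = (30.0,),
    conditions: tuple[str, str] = ("plus_T7", "minus_T7"),
    test_pair: str = "a:c",
    control_pair: str = "a:b",
) -> pd.DataFrame:
    """Synthetic 3C band table with a known interaction-frequency ratio.

    The test-pair ligation frequency in the first (numerator) condition is
    ``true_ratio`` times its value in the second; the control pair is
    condition-independent. Intensities scale linearly with template mass
    and carry multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (unit mean, so ratios are recovered in expectation).
    """
    if not true_ratio > 0:
        raise DomainError(f"true_ratio must be > 0, got {true_ratio}")
    if noise_cv < 0:
        raise DomainError(f"noise_cv must be >= 0, got {noise_cv}")
    eff = dict(primer_efficiencies or {})
    scale = dict(condition_scales or {})
    for pair in (test_pair, control_pair):
        eff.setdefault(pair, 1.0)
    for cond in conditions:
        scale.setdefault(cond, 1.0)
    if any(v <= 0 for v in list(eff.values()) + list(scale.values())):
        raise DomainError("efficiencies and scales must be > 0")

    # unit-mean lognormal: exp(N(-s^2/2, s)) with s^2 = ln(1 + cv^2)
    s = float(np.sqrt(np.log1p(noise_cv**2)))
    rng = np.random.default_rng(seed)

    ligation = {
        (conditions[0], test_pair): true_ratio,
        (conditions[1], test_pair): 1.0,
        (conditions[0], control_pair): 1.0,
        (conditions[1], control_pair): 1.0,
    }
    ref_mass = float(masses[0])
    rows = []
    for cond in conditions:
        for pair in (test_pair, control_pair):
            for mass in masses:
                for rep in range(1, replicates + 1):
                    mean = (
                        eff[pair]
                        * scale[cond]
                        * ligation[(cond, pair)]
                        * mass
                        / ref_mass
                    )
                    noise = np.exp(rng.normal(-0.5 * s * s, s)) if s > 0 else 1.0
                    rows.append(
                        {
                            "condition": cond,
                            "primer_pair": pair,
                            "template_mass_ng": float(mass),
                            "replicate": rep,
                            "intensity": mean * noise,
                        }
                    )
    return pd.DataFrame(rows)
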