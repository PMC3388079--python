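"""3C (chromosome conformation capture) band-intensity quantification.

A 3C experiment reports the contact frequency of two genomic loci through
the ligation frequency of their restriction fragments, read out as PCR
band intensities on a gel. Raw intensities confound three factors:

    intensity = primer-pair efficiency x ligation frequency x per-sample scale

Dividing a test-pair intensity by a control-pair intensity *within* a
sample cancels the per-sample scale ("test gene contact frequency");
dividing that ratio between conditions cancels the primer efficiencies as
well, leaving the pure change in interaction frequency. Both
cancellations hold for any positive multipliers, which the tests exercise
as metamorphic properties.

Band tables are plain DataFrames with columns
``condition, primer_pair, template_mass_ng, replicate, intensity``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SchemaError

__all__ = [
    "BAND_COLUMNS",
    "ContactRatio",
    "validate_band_table",
    "contact_frequency",
    "condition_ratio",
    "linearity_check",
    "digestion_efficiency",
]

logger = logging.getLogger(__name__)

BAND_COLUMNS = ("condition", "primer_pair", "template_mass_ng", "replicate", "intensity")


@dataclass(frozen=True)
class ContactRatio:
    """A normalized contact-frequency ratio with propagated uncertainty."""

    value: float
    sd: float
    numerator: str
    denominator: str
    normalizer: str = ""


def validate_band_table(bands: pd.DataFrame) -> pd.DataFrame:
    """Check the band-table schema and invariants; returns the table."""
    missing = [c for c in BAND_COLUMNS if c not in bands.columns]
    if missing:
        raise SchemaError(f"band table missing column(s): {', '.join(missing)}")
    if (bands["intensity"] < 0).any():
        raise SchemaError("band intensities must be >= 0")
    keys = ["condition", "primer_pair", "template_mass_ng", "replicate"]
    if bands.duplicated(subset=keys).any():
        dup = bands[bands.duplicated(subset=keys, keep=False)]
        raise SchemaError(
            f"duplicate (condition, primer_pair, mass, replicate) rows:\n{dup}"
        )
    return bands


def _reference_mass(sub: pd.DataFrame, template_mass: float | None) -> float:
    if template_mass is not None:
        return template_mass
    # the 1x loading is the modal mass across the table
    return float(sub["template_mass_ng"].mode().iloc[0])


def _replicate_stats(
    bands: pd.DataFrame, condition: str, pair: str, mass: float
) -> tuple[float, float, int]:
    sel = bands[
        (bands["condition"] == condition)
        & (bands["primer_pair"] == pair)
        & np.isclose(bands["template_mass_ng"], mass)
    ]
    if sel.empty:
        raise SchemaError(
            f"no bands for condition={condition!r}, primer_pair={pair!r}, "
            f"template_mass_ng={mass}"
        )
    vals = sel["intensity"].to_numpy(dtype=float)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, vals.size


def contact_frequency(
    bands: pd.DataFrame,
    condition: str,
    test_pair: str,
    control_pair: str,
    template_mass: float | None = None,
) -> ContactRatio:
    """Within-sample contact frequency: mean test-pair intensity divided
    by mean control-pair intensity at the reference template mass
    (ratio of replicate means, with first-order error propagation)."""
    validate_band_table(bands)
    sub = bands[bands["condition"] == condition]
    if sub.empty:
        raise SchemaError(f"condition {condition!r} not present in band table")
    mass = _reference_mass(sub, template_mass)
    m_test, s_test, _ = _replicate_stats(bands, condition, test_pair, mass)
    m_ctrl, s_ctrl, _ = _replicate_stats(bands, condition, control_pair, mass)
    if m_ctrl == 0:
        raise ZeroDivisionError(
            f"control pair {control_pair!r} has zero mean intensity in "
            f"condition {condition!r}; cannot normalize"
        )
    value = m_test / m_ctrl
    sd = abs(value) * math.sqrt(
        (s_test / m_test) ** 2 + (s_ctrl / m_ctrl) ** 2
    ) if m_test != 0 else s_test / m_ctrl
    return ContactRatio(
        value=value, sd=sd, numerator=condition, denominator=condition,
        normalizer=control_pair,
    )


def condition_ratio(
    bands: pd.DataFrame,
    test_pair: str,
    control_pair: str,
    numerator_condition: str = "plus_T7",
    denominator_condition: str = "minus_T7",
    template_mass: float | None = None,
) -> ContactRatio:
    """Between-condition change in interaction frequency.

    Equal to contact_frequency(numerator)/contact_frequency(denominator);
    invariant both to per-primer-pair efficiencies applied identically
    across conditions and to per-condition global scales.
    """
    num = contact_frequency(bands, numerator_condition, test_pair, control_pair,
                            template_mass=template_mass)
    den = contact_frequency(bands, denominator_condition, test_pair, control_pair,
                            template_mass=template_mass)
    if den.value == 0:
        raise ZeroDivisionError(
            f"contact frequency in {denominator_condition!r} is zero"
        )
    value = num.value / den.value
    rel = 0.0
    if num.value != 0:
        rel = (num.sd / num.value) ** 2 + (den.sd / den.value) ** 2
    return ContactRatio(
        value=value,
        sd=abs(value) * math.sqrt(rel),
        numerator=numerator_condition,
        denominator=denominator_condition,
        normalizer=control_pair,
    )


def linearity_check(
    bands: pd.DataFrame,
    primer_pair: str,
    condition: str | None = None,
    r2_threshold: float = 0.95,
    intercept_tol: float = 0.1,
) -> tuple[float, float, float, bool]:
    """Dilution-series linearity control.

    Regresses intensity on template mass over the dilution series (e.g.
    0.5x, 1x, 2x loadings) and passes when r^2 >= ``r2_threshold`` and the
    intercept is within ``intercept_tol`` of zero, measured relative to
    the fitted intensity at the largest mass. Returns
    (slope, intercept, r2, passed).
    """
    validate_band_table(bands)
    sub = bands[bands["primer_pair"] == primer_pair]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if sub["template_mass_ng"].nunique() < 3:
        raise DomainError(
            f"linearity check needs >= 3 template masses for {primer_pair!r}, "
            f"got {sub['template_mass_ng'].nunique()}"
        )
    x = sub["template_mass_ng"].to_numpy(dtype=float)
    y = sub["intensity"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        # saturated gel: identical intensities at every loading
        return 0.0, float(y[0]), 0.0, False
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    top = fit.slope * x.max() + fit.intercept
    intercept_ok = top != 0 and abs(fit.intercept) <= intercept_tol * abs(top)
    passed = bool(r2 >= r2_threshold and intercept_ok)
    return float(fit.slope), float(fit.intercept), r2, passed


def digestion_efficiency(
    cut_site_ratio_digested: float, cut_site_ratio_undigested: float
) -> float:
    """Restriction-digestion efficiency from the ratio of a cut-site-
    spanning amplicon to a total-DNA amplicon, with and without digestion:
    efficiency = 1 - digested/undigested, clamped to [0, 1]."""
    if not cut_site_ratio_digested >= 0:
        raise DomainError(
            f"digested ratio must be >= 0, got {cut_site_ratio_digested}"
        )
    if not cut_site_ratio_undigested > 0:
        raise DomainError(
            f"undigested ratio must be > 0, got {cut_site_ratio_undigested}"
        )
    eff = 1.0 - cut_site_ratio_digested / cut_site_ratio_undigested
    if eff < 0.0:
        warnings.warn(
            f"digestion efficiency {eff:.3g} below 0; clamping", stacklevel=2
        )
        eff = 0.0
    return eff
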