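"""Closed-form monomer-dimer equilibrium.

For 2 M <-> M2 with dissociation constant Kd = [M]^2/[M2] and total
molecule concentration C = [M] + 2[M2], the free monomer is the positive
root of the quadratic 2 m^2/Kd + m - C = 0:

    m = (-Kd + sqrt(Kd^2 + 8 Kd C)) / 4

The quantity of interest downstream is the fraction of *molecules*
residing in dimers, 2[M2]/C: under trace labeling (a few nM labeled
molecules amid a large unlabeled excess) this equals the probability that
a labeled molecule sits in a dimer, which is what an FCS mixture model
needs as the slow-species number fraction.

An alternative convention treats the labeled species as an infinitely
dilute partner binding the free unlabeled monomer pool, giving a bound
fraction m/(Kd + m); it predicts a noticeably smaller bound fraction and
is provided for comparison but is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = ["DimerEquilibrium", "solve_monomer_dimer", "trace_bound_fraction"]


@dataclass(frozen=True)
class DimerEquilibrium:
    """Equilibrium composition of a monomer-dimer system (all
    concentrations in uM)."""

    c_total: float
    kd: float
    monomer: float
    dimer: float
    frac_molecules_in_dimers: float


def solve_monomer_dimer(c_total: float, kd: float) -> DimerEquilibrium:
    """Solve the monomer-dimer equilibrium in closed form.

    Parameters
    ----------
    c_total : float
        Total molecule concentration, uM (monomers + 2x dimers).
    kd : float
        Dissociation constant, uM.
    """
    if c_total < 0:
        raise DomainError(f"c_total must be >= 0, got {c_total}")
    if not kd > 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    if c_total == 0:
        return DimerEquilibrium(0.0, kd, 0.0, 0.0, 0.0)
    m = (-kd + math.sqrt(kd * kd + 8.0 * kd * c_total)) / 4.0
    d = m * m / kd
    return DimerEquilibrium(
        c_total=c_total,
        kd=kd,
        monomer=m,
        dimer=d,
        frac_molecules_in_dimers=2.0 * d / c_total,
    )


def trace_bound_fraction(c_unlabeled: float, kd: float) -> float:
    """Bound fraction of an infinitely dilute labeled species:
    m/(Kd + m), with m the free monomer of the unlabeled pool."""
    if c_unlabeled < 0:
        raise DomainError(f"c_unlabeled must be >= 0, got {c_unlabeled}")
    if c_unlabeled == 0:
        return 0.0
    m = solve_monomer_dimer(c_unlabeled, kd).monomer
    return m / (kd + m)
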