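"""Equilibrium occupancy of HSA ligand-binding sites.

Two models are provided and the reporting layer says which was used:

* ``occupancy_simple`` -- the Langmuir isotherm theta = K*L / (1 + K*L),
  valid when total ligand far exceeds total binding sites, so free ligand
  equals total ligand.
* ``occupancy_depletion`` -- the exact single-class mass balance. With
  total site concentration S = n_sites * [HSA], dissociation constant
  Kd = 1/K and total ligand L, the bound concentration solves
  b^2 - (S + L + Kd) b + S*L = 0, taking the physical root
  b = ((S + L + Kd) - sqrt((S + L + Kd)^2 - 4*S*L)) / 2, theta = b / S.
  This matters for poorly soluble ligands (e.g. levothyroxine at 15 uM
  against up to 160 uM of sites) where the ligand pool is depleted.

Site classes are treated independently (no competition between classes for
the same ligand pool). Rounding to the nearest percent, half away from
zero, happens only at the reporting layer (:func:`to_percent`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OccupancySpec",
    "occupancy_simple",
    "occupancy_depletion",
    "occupancy_over_range",
    "to_percent",
]


@dataclass(frozen=True)
class OccupancySpec:
    """One site class at one protein/ligand condition.

    K : association constant, M^-1; n_sites : sites of this class per HSA
    molecule; hsa_conc, ligand_conc : total concentrations, M.
    """

    K: float
    ligand_conc: float
    hsa_conc: float = 0.0
    n_sites: int = 1

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("association constant K must be > 0")
        if self.ligand_conc < 0 or self.hsa_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def occupancy_simple(K: float, ligand_conc: float) -> float:
    """Excess-ligand isotherm theta = K*L / (1 + K*L)."""
    if K <= 0:
        raise ValueError("K must be > 0")
    if ligand_conc < 0:
        raise ValueError("ligand concentration must be >= 0")
    kl = K * ligand_conc
    return kl / (1.0 + kl)


def occupancy_depletion(spec: OccupancySpec) -> float:
    """Exact single-class mass-balance occupancy (ligand depletion allowed)."""
    s = spec.n_sites * spec.hsa_conc
    if s == 0:
        return occupancy_simple(spec.K, spec.ligand_conc)
    kd = 1.0 / spec.K
    ell = spec.ligand_conc
    p = s + ell + kd
    disc = p * p - 4.0 * s * ell
    assert disc >= 0.0, "mass-balance discriminant negative (invalid inputs)"
    bound = (p - math.sqrt(disc)) / 2.0
    return bound / s


def occupancy_over_range(
    K: float,
    ligand_conc: float,
    hsa_range: tuple[float, float],
    n_sites: int = 1,
) -> tuple[float, float]:
    """Occupancy at the endpoints of an HSA concentration range, sorted.

    Occupancy is monotone decreasing in total site concentration at fixed
    total ligand, so the endpoints bracket the range.
    """
    lo, hi = hsa_range
    if lo > hi:
        lo, hi = hi, lo
    thetas = [
        occupancy_depletion(OccupancySpec(K, ligand_conc, h, n_sites))
        for h in (lo, hi)
    ]
    return (min(thetas), max(thetas))


def to_percent(theta: float) -> int:
    """Report a fraction as a whole percent, half away from zero."""
    return int(math.floor(100.0 * theta + 0.5))
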