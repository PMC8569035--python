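"""Compton-scattering energy-angle relations.

The Compton camera measures two energy deposits per photon: the recoil
electron energy ``E1`` left in a silicon scatterer layer and the energy
``E2`` photo-absorbed in a CdTe layer.  For a photon that deposited its
full energy, the scattering angle theta follows from

    cos(theta) = 1 - m_e c^2 * E1 / (E2 * (E1 + E2))

with ``m_e c^2`` the electron rest energy.  The same relation, inverted,
gives the energy split for a known incident energy and angle; both
directions live here so the event generator and the reconstructor share
one set of constants.

All functions broadcast over numpy arrays; angles cross the API in
degrees (instrument specs quote degrees), radians are used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Electron rest energy in keV.
ELECTRON_MASS_KEV = 511.0

#: Conversion between a Gaussian FWHM and its standard deviation.
FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass(frozen=True)
class EnergyPair:
    """Energies (keV) deposited by one Compton event.

    Attributes
    ----------
    e_scatter : float or ndarray
        Recoil-electron energy deposited in the scatterer (E1).
    e_absorb : float or ndarray
        Energy deposited in the absorber (E2).
    """

    e_scatter: float
    e_absorb: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.e_scatter) < 0):
            raise ValueError("scatterer energy must be non-negative")
        if np.any(np.asarray(self.e_absorb) < 0):
            raise ValueError("absorber energy must be non-negative")

    def total(self):
        """Summed deposited energy E1 + E2 (keV)."""
        return self.e_scatter + self.e_absorb


def compute_cos_theta(pair: EnergyPair):
    """Cosine of the Compton scattering angle implied by an energy pair.

    The value may fall outside [-1, 1] for pairs that are not consistent
    with a single full-energy Compton event (e.g. partial deposits); the
    caller decides validity via :func:`is_kinematically_valid`.

    Raises
    ------
    ZeroDivisionError
        If the absorber energy or the summed energy is zero.
    """
    e1 = np.asarray(pair.e_scatter, dtype=float)
    e2 = np.asarray(pair.e_absorb, dtype=float)
    total = e1 + e2
    if np.any(e2 == 0) or np.any(total == 0):
        raise ZeroDivisionError("absorber or total energy is zero; cos(theta) undefined")
    out = 1.0 - ELECTRON_MASS_KEV * e1 / (e2 * total)
    return float(out) if out.ndim == 0 else out


def is_kinematically_valid(pair: EnergyPair, tol: float = 1e-9):
    """Whether the pair's cosine lies in [-1, 1] (within ``tol``).

    Pairs failing this cannot form a Compton cone and must be discarded
    before reconstruction.
    """
    c = compute_cos_theta(pair)
    return np.abs(np.asarray(c)) <= 1.0 + tol if np.ndim(c) else abs(c) <= 1.0 + tol


def split_energy(e0, theta_deg) -> EnergyPair:
    """Forward Compton split of an incident energy at a given angle.

    ``E2 = E0 / (1 + (E0/511)(1 - cos theta))`` is the scattered-photon
    energy (fully absorbed downstream), ``E1 = E0 - E2`` the recoil
    energy.  The pair sums to ``e0`` exactly and round-trips through
    :func:`compute_cos_theta`.
    """
    e0 = np.asarray(e0, dtype=float)
    cos_t = np.cos(np.deg2rad(np.asarray(theta_deg, dtype=float)))
    e2 = e0 / (1.0 + (e0 / ELECTRON_MASS_KEV) * (1.0 - cos_t))
    e1 = e0 - e2
    if e1.ndim == 0:
        return EnergyPair(float(e1), float(e2))
    return EnergyPair(e1, e2)


def two_point_resolution(angular_res_deg: float, distance_mm: float) -> float:
    """Spatial two-point resolution (mm) at a given standoff distance.

    Small-angle arc length: the angular resolution measure (FWHM,
    degrees) times the source-to-camera distance.  5 degrees at 140 mm
    gives 12.2 mm.
    """
    if angular_res_deg < 0 or distance_mm <= 0:
        raise ValueError("angular resolution must be >= 0 and distance > 0")
    return distance_mm * math.radians(angular_res_deg)
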