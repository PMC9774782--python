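"""Antioxidant distributions and effective concentrations from partition constants.

Once P_O^I is known, the fraction of a water-insoluble antioxidant in each
region follows directly from the mass balance over the two accessible
regions:

    %AO_I = 100 * Phi_I * P_O^I / (Phi_O + Phi_I * P_O^I)
    %AO_O = 100 * Phi_O        / (Phi_O + Phi_I * P_O^I)

and the effective (per-region) concentrations are the stoichiometric
concentration rescaled by occupancy over region volume, e.g. for the
interface (AO_I) = [AO_T] * (%AO_I/100) / Phi_I. The ratio
(AO_I) / [AO_T] is the fold-enrichment of the antioxidant at the
interface — typically one to two orders of magnitude, because the
interfacial region is a small fraction of the emulsion volume.

A non-obvious consequence, surfaced by :func:`distribution_profile`: as
surfactant is added, %AO_I rises but (AO_I) falls, because the interfacial
volume grows faster than the interfacial occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedConcentrationError
from .pkm import EmulsionComposition

__all__ = [
    "DistributionProfile",
    "percent_interfacial",
    "percent_oil",
    "invert_percent_interfacial",
    "effective_interfacial_concentration",
    "effective_oil_concentration",
    "distribution_profile",
]


def percent_interfacial(P_O_I: float, comp: EmulsionComposition) -> float:
    """Percentage of antioxidant in the interfacial region (0-100 scale)."""
    if not P_O_I > 0:
        raise ValueError("P_O_I must be positive")
    return 100.0 * comp.phi_I * P_O_I / (comp.phi_O + comp.phi_I * P_O_I)


def percent_oil(P_O_I: float, comp: EmulsionComposition) -> float:
    """Percentage of antioxidant in the oil region; complements %AO_I to 100."""
    if not P_O_I > 0:
        raise ValueError("P_O_I must be positive")
    return 100.0 * comp.phi_O / (comp.phi_O + comp.phi_I * P_O_I)


def invert_percent_interfacial(pct_I: float, comp: EmulsionComposition) -> float:
    """Partition constant implied by an observed interfacial percentage.

    Inverts the interfacial mass-balance at a single composition:
    P_O^I = (pct/(100 - pct)) * Phi_O / Phi_I. Useful for anchoring the
    model to a single measured distribution point.
    """
    if not 0.0 < pct_I < 100.0:
        raise ValueError("pct_I must lie strictly between 0 and 100")
    if comp.phi_I <= 0:
        raise UndefinedConcentrationError("phi_I must be positive to invert")
    return (pct_I / (100.0 - pct_I)) * comp.phi_O / comp.phi_I


def effective_interfacial_concentration(AO_T: float, pct_I: float, phi_I: float) -> float:
    """Moles of antioxidant per liter of interfacial region.

    (AO_I) = [AO_T] * (%AO_I / 100) / Phi_I — the stoichiometric
    concentration concentrated into the interfacial volume.
    """
    if phi_I <= 0:
        raise UndefinedConcentrationError("phi_I = 0: interfacial concentration undefined")
    if not 0.0 <= pct_I <= 100.0:
        raise ValueError("pct_I must be in [0, 100]")
    return AO_T * (pct_I / 100.0) / phi_I


def effective_oil_concentration(AO_T: float, pct_O: float, phi_O: float) -> float:
    """Moles of antioxidant per liter of oil region."""
    if phi_O <= 0:
        raise UndefinedConcentrationError("phi_O = 0: oil concentration undefined")
    if not 0.0 <= pct_O <= 100.0:
        raise ValueError("pct_O must be in [0, 100]")
    return AO_T * (pct_O / 100.0) / phi_O


@dataclass(frozen=True)
class DistributionProfile:
    """Distribution and effective concentrations over a grid of Phi_I.

    All arrays align with ``phi_I_grid``. ``fold_I`` is conc_I / AO_T, the
    interfacial enrichment over the stoichiometric concentration.
    ``dilution_with_surfactant`` flags the characteristic pattern in which
    pct_I rises across the grid while conc_I falls.
    """

    phi_I_grid: np.ndarray
    pct_I: np.ndarray
    pct_O: np.ndarray
    conc_I: np.ndarray  # M, per liter of interfacial region
    conc_O: np.ndarray  # M, per liter of oil region
    fold_I: np.ndarray
    AO_T: float
    phi_O: np.ndarray
    P_O_I: float
    dilution_with_surfactant: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phi_I": self.phi_I_grid,
                "pct_I": self.pct_I,
                "pct_O": self.pct_O,
                "conc_I_M": self.conc_I,
                "conc_O_M": self.conc_O,
                "fold_I": self.fold_I,
            }
        )


def distribution_profile(
    P_O_I: float,
    AO_T: float,
    phi_I_grid,
    phi_O=0.1,
) -> DistributionProfile:
    """Evaluate distribution percentages and effective concentrations on a grid.

    Parameters
    ----------
    P_O_I:
        Oil-interface partition constant.
    AO_T:
        Stoichiometric antioxidant concentration, M (per liter of emulsion).
    phi_I_grid:
        Sorted, positive interfacial volume fractions.
    phi_O:
        Oil volume fraction — a scalar held constant across the grid
        (default 0.1, a 1:9 v/v emulsion) or one value per grid point.
    """
    grid = np.atleast_1d(np.asarray(phi_I_grid, dtype=float))
    if np.any(grid <= 0):
        raise ValueError("phi_I grid values must be positive")
    if np.any(np.diff(grid) < 0):
        raise ValueError("phi_I grid must be sorted ascending")
    phi_O_arr = np.broadcast_to(np.asarray(phi_O, dtype=float), grid.shape).copy()

    pct_I = np.empty_like(grid)
    pct_O = np.empty_like(grid)
    for i, (fi, fo) in enumerate(zip(grid, phi_O_arr)):
        comp = EmulsionComposition(phi_O=fo, phi_I=fi, phi_W=1.0 - fo - fi)
        pct_I[i] = percent_interfacial(P_O_I, comp)
        pct_O[i] = percent_oil(P_O_I, comp)
    conc_I = AO_T * (pct_I / 100.0) / grid
    conc_O = AO_T * (pct_O / 100.0) / phi_O_arr
    fold_I = conc_I / AO_T

    diluting = bool(
        grid.size > 1
        and np.all(np.diff(pct_I) > 0)
        and np.all(np.diff(conc_I) < 0)
    )
    return DistributionProfile(
        phi_I_grid=grid,
        pct_I=pct_I,
        pct_O=pct_O,
        conc_I=conc_I,
        conc_O=conc_O,
        fold_I=fold_I,
        AO_T=AO_T,
        phi_O=phi_O_arr,
        P_O_I=P_O_I,
        dilution_with_surfactant=diluting,
    )
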