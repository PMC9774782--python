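"""Synthetic study generator for the pseudophase kinetic pipeline.

Emulates a full surfactant-titration / acidity study on a Tween-20
stabilized 1:9 (v/v) oil-in-water emulsion so every pipeline stage can be
exercised without laboratory data:

* first-order absorbance decays for the derivatization assay,
* k_obs vs Phi_I series obeying the two-region rate law with multiplicative
  lognormal noise at the assay's replicate precision (CV ~8%),
* multi-pH bundles in which the planted partition constant is held fixed
  while k_I scales ten-fold per pH unit (the inverse-[H+] law).

Defaults mirror the reference experimental design: [AO_T] = 0.004 M,
Phi_O = 0.1, eight surfactant levels spanning Phi_I = 0.005-0.04
(Tween 20 at 0.5-4% w/w), pH 3-6, triplicate runs. Every stochastic call
takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CompositionError
from .pkm import EmulsionComposition, KineticSeries, kobs_forward
from .traces import AbsorbanceTrace

__all__ = [
    "SyntheticSpec",
    "composition_from_surfactant",
    "make_trace",
    "make_kinetic_series",
    "make_ph_study",
]

_LN2 = math.log(2.0)


def _default_phi_I_levels() -> tuple:
    # Eight levels, geometric over the experimental span (the surfactant
    # mass series 0.5, 1, 2, 4 %w/w is itself geometric).
    return tuple(np.geomspace(0.005, 0.04, 8))


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted ground truth and design for a synthetic study.

    ``true_k_I_ref`` is the interfacial rate constant at the reference
    acidity ``pH_ref``; at other acidities k_I = true_k_I_ref *
    10**(pH - pH_ref), the inverse-[H+] law. ``noise_cv`` is the relative
    standard deviation of the multiplicative lognormal noise applied to
    each replicate k_obs (assay precision is 7-9%, hence the 0.08 default).
    """

    seed: int
    true_P_O_I: float = 5.0
    true_k_I_ref: float = 1.0  # M^-1 s^-1 at pH_ref
    AO_T: float = 0.004  # M
    phi_O: float = 0.1
    phi_I_levels: tuple = field(default_factory=_default_phi_I_levels)
    pH_levels: tuple = (3.0, 4.0, 5.0, 6.0)
    pH_ref: float = 3.0
    noise_cv: float = 0.08
    n_replicates: int = 3

    def __post_init__(self):
        if not 0.0 <= self.noise_cv <= 0.2:
            raise ValueError("noise_cv must be in [0, 0.2]")
        if any(v <= 0 for v in self.phi_I_levels):
            raise ValueError("phi_I levels must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (self.true_P_O_I > 0 and self.true_k_I_ref > 0 and self.AO_T > 0):
            raise ValueError("planted parameters must be positive")

    def k_I_at(self, pH: float) -> float:
        return self.true_k_I_ref * 10.0 ** (pH - self.pH_ref)


def composition_from_surfactant(
    surfactant_wt_frac: float,
    surfactant_density: float = 1.11,  # g/mL (Tween 20)
    oil_to_water: tuple = (1, 9),
    total_volume_mL: float = 10.0,
) -> EmulsionComposition:
    """Emulsion composition from the surfactant mass fraction.

    The interfacial volume fraction is the surfactant volume over the total
    volume, Phi_I = (w * m_emulsion / rho_surf) / V_T, taking the emulsion
    density as 1.00 g/mL for the mass-to-volume conversion (an
    approximation: only the surfactant density is specified). The oil
    fraction is the nominal ratio (0.1 for 1:9 v/v) and the aqueous
    fraction closes the balance.
    """
    if not 0.0 < surfactant_wt_frac < 0.1:
        raise CompositionError(
            f"surfactant weight fraction {surfactant_wt_frac} outside (0, 0.1)"
        )
    emulsion_mass_g = total_volume_mL * 1.00
    v_surf_mL = surfactant_wt_frac * emulsion_mass_g / surfactant_density
    phi_I = v_surf_mL / total_volume_mL
    oil, water = oil_to_water
    phi_O = oil / (oil + water)
    phi_W = 1.0 - phi_O - phi_I
    return EmulsionComposition(
        phi_O=phi_O, phi_I=phi_I, phi_W=phi_W, surfactant_label="Tween 20"
    )


def make_trace(
    k_obs: float,
    A0: float,
    Ainf: float,
    duration_halflives: float = 3.0,
    n_points: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> AbsorbanceTrace:
    """Exact first-order decay plus independent Gaussian absorbance noise."""
    if not k_obs > 0:
        raise ValueError("k_obs must be positive")
    duration = duration_halflives * _LN2 / k_obs
    t = np.linspace(0.0, duration, n_points)
    a = Ainf + (A0 - Ainf) * np.exp(-k_obs * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=n_points)
    return AbsorbanceTrace(times=t, absorbances=np.clip(a, 0.0, None), label=label)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # Mean-one lognormal with sd/mean = cv exactly.
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def make_kinetic_series(spec: SyntheticSpec, pH: float | None = None) -> KineticSeries:
    """k_obs observations over the surfactant levels at one acidity.

    Each phi_I level yields ``n_replicates`` observations: the exact
    forward-model rate constant multiplied by mean-one lognormal noise of
    the requested CV. The random stream is derived from (seed, pH) so
    different acidities of the same study are independent yet reproducible.
    """
    if pH is None:
        pH = spec.pH_ref
    k_I = spec.k_I_at(pH)
    rng = np.random.default_rng([spec.seed, int(round(pH * 1000))])
    obs = []
    for phi_I in spec.phi_I_levels:
        comp = EmulsionComposition(
            phi_O=spec.phi_O, phi_I=phi_I, phi_W=1.0 - spec.phi_O - phi_I
        )
        k_true = kobs_forward(spec.true_P_O_I, comp, spec.AO_T, k_I)
        factors = _lognormal_factors(rng, spec.noise_cv, spec.n_replicates)
        for f in factors:
            obs.append((phi_I, spec.phi_O, k_true * float(f)))
    return KineticSeries(
        observations=tuple(obs), AO_T=spec.AO_T, pH=float(pH),
        antioxidant_label="synthetic", oil_label="synthetic",
    )


def make_ph_study(spec: SyntheticSpec) -> dict:
    """One kinetic series per pH level, sharing the planted P_O^I.

    Partition constants are acidity-independent by construction while k_I
    follows the inverse-[H+] law, so a correct downstream analysis must
    recover constant P and ten-fold k_I steps per pH unit.
    """
    if len(spec.pH_levels) < 1:
        raise ValueError("need at least one pH level")
    return {float(pH): make_kinetic_series(spec, pH) for pH in spec.pH_levels}
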