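"""Acidity dependence of the interfacial rate constant.

Both coupling routes between the aryldiazonium probe and a phenolic
antioxidant proceed through the phenolate ion, so well below the
antioxidant's pKa the intrinsic interfacial rate constant scales as
k_I ∝ 1/[H+]: log10(k_I) vs pH is a line of theoretical slope 1.
Observed slopes slightly below 1 (0.8-0.9) are typical.

The same study design supports the model's headline sensitivity check:
changing acidity is a pure medium effect, so fitted partition constants
(concentration effects) must stay constant across pH while k_I scales
ten-fold per pH unit. :func:`partition_acidity_invariance` tests that
decoupling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDesignError
from .pkm import PKMFit

__all__ = [
    "PHSeries",
    "MechanismVerdict",
    "InvarianceVerdict",
    "fit_log_ki_vs_ph",
    "mechanism_consistency",
    "partition_acidity_invariance",
]


@dataclass(frozen=True)
class PHSeries:
    """Log-linear fit of interfacial rate constants across acidity.

    ``entries`` are (pH, k_I) or (pH, k_I, se_kI) tuples; ``slope`` is in
    log10 units per pH unit (1 for a pure inverse-[H+] mechanism).
    """

    entries: tuple
    slope: float
    intercept: float  # log10(k_I) extrapolated to pH 0
    r_squared: float
    slope_se: float


@dataclass(frozen=True)
class MechanismVerdict:
    consistent: bool
    slope: float
    expected_slope: float
    deviation: float
    tol: float


@dataclass(frozen=True)
class InvarianceVerdict:
    invariant: bool
    max_discrepancy_z: float | None  # largest pairwise |dP| / pooled se
    relative_spread: float
    method: str  # "pooled-se" | "relative-spread"
    P_values: tuple


def fit_log_ki_vs_ph(entries) -> PHSeries:
    """OLS of log10(k_I) on pH.

    Requires at least 3 distinct pH values and positive rate constants.
    """
    entries = tuple(tuple(float(x) for x in e) for e in entries)
    ph = np.array([e[0] for e in entries])
    ki = np.array([e[1] for e in entries])
    if np.unique(ph).size < 3:
        raise InsufficientDesignError("need >= 3 distinct pH values")
    if np.any(ki <= 0):
        raise ValueError("all k_I must be positive to take logarithms")
    res = stats.linregress(ph, np.log10(ki))
    return PHSeries(
        entries=entries,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
    )


def mechanism_consistency(
    series: PHSeries, expected_slope: float = 1.0, tol: float = 0.25
) -> MechanismVerdict:
    """Is the fitted acidity slope consistent with the phenolate mechanism?

    Consistent iff |slope - expected_slope| <= tol. The default tolerance
    of 0.25 brackets the slopes typically observed for these couplings
    (0.8-0.92 against a theoretical 1).
    """
    dev = abs(series.slope - expected_slope)
    return MechanismVerdict(
        consistent=dev <= tol,
        slope=series.slope,
        expected_slope=expected_slope,
        deviation=dev,
        tol=tol,
    )


def partition_acidity_invariance(
    fits,
    z: float | None = None,
    family_alpha: float = 0.05,
    relative_spread_tol: float = 0.20,
) -> InvarianceVerdict:
    """Test whether fitted partition constants are constant across acidity.

    Partitioning is thermodynamic, so a change in acidity (a medium effect
    acting on k_I) must leave P_O^I unchanged; this is the decisive check
    that the model separates medium from concentration effects.

    Every pair of acidities is compared: invariant iff
    |P_i - P_j| <= z * sqrt(se_i^2 + se_j^2) for all pairs.

    Parameters
    ----------
    fits:
        PKM fits at two or more acidities.
    z:
        Pairwise critical value. By default it is the Sidak-corrected
        two-sided normal quantile for the number of pairs at
        ``family_alpha``, so the whole screen falsely flags a truly
        constant P in only ~``family_alpha`` of studies regardless of how
        many acidities were run (a fixed z per pair would let the
        false-alarm rate grow with the number of pairs). Pass an explicit
        z (e.g., 2.0) to use a raw per-pair rule instead.
    family_alpha:
        Family-wise false-alarm rate used to derive the default z.
    relative_spread_tol:
        Fallback when standard errors are missing: invariant iff
        (max - min)/mean <= this threshold (with a warning).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InsufficientDesignError(
            "need fits at >= 2 acidities to assess invariance"
        )
    n_pairs = len(fits) * (len(fits) - 1) // 2
    if z is None:
        pair_alpha = 1.0 - (1.0 - family_alpha) ** (1.0 / n_pairs)
        z = float(stats.norm.ppf(1.0 - pair_alpha / 2.0))
    P = np.array([f.P_O_I for f in fits])
    se = np.array([f.se_P if f.se_P is not None else np.nan for f in fits])
    spread = float((P.max() - P.min()) / P.mean())

    if np.all(np.isfinite(se)) and np.all(se > 0):
        max_z = 0.0
        for i, j in itertools.combinations(range(len(fits)), 2):
            pooled = float(np.hypot(se[i], se[j]))
            max_z = max(max_z, abs(P[i] - P[j]) / pooled)
        return InvarianceVerdict(
            invariant=max_z <= z,
            max_discrepancy_z=max_z,
            relative_spread=spread,
            method="pooled-se",
            P_values=tuple(P),
        )

    warnings.warn(
        "standard errors missing; falling back to relative-spread criterion",
        stacklevel=2,
    )
    return InvarianceVerdict(
        invariant=spread <= relative_spread_tol,
        max_discrepancy_z=None,
        relative_spread=spread,
        method="relative-spread",
        P_values=tuple(P),
    )
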