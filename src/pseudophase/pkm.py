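"""The two-region pseudophase kinetic model (PKM).

An oil-in-water emulsion is treated as three thermodynamic pseudophases —
oil (O), interfacial (I), and aqueous (W) — in dynamic equilibrium, with
volume fractions Phi_O + Phi_I + Phi_W = 1. A water-insoluble antioxidant
(e.g., a tocopherol) partitions only between oil and interface, described
by the partition constant

    P_O^I = (AO_I) / (AO_O),

a ratio of effective concentrations (moles per liter of the particular
region). The chemical probe reacts with the antioxidant exclusively in the
interfacial region with intrinsic second-order rate constant k_I, giving
the observed pseudo-first-order rate constant

    k_obs = [AO_T] k_I P_O^I / (Phi_I P_O^I + Phi_O),

where [AO_T] is the stoichiometric antioxidant concentration (moles per
liter of total emulsion). Taking reciprocals linearizes the model:

    1/k_obs = Phi_O / (k_I [AO_T] P_O^I) + Phi_I / (k_I [AO_T]),

so a plot of 1/k_obs against Phi_I is a line with positive slope and
positive intercept; k_I comes from the slope and P_O^I from the
slope/intercept ratio. A direct nonlinear refit of the untransformed rate
law is also provided, since the reciprocal transform inflates the noise of
the smallest k_obs values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    CompositionError,
    ConsistencyViolationError,
    FitFailureError,
    InsufficientDesignError,
    ModelMisfitError,
)

__all__ = [
    "EmulsionComposition",
    "PartitionSet",
    "KineticSeries",
    "PKMFit",
    "kobs_forward",
    "fit_reciprocal",
    "fit_nonlinear",
    "partition_consistency",
]


@dataclass(frozen=True)
class EmulsionComposition:
    """Volume fractions of the three emulsion regions.

    ``phi_I`` may be zero (a surfactant-free binary oil-water system); the
    three fractions must close to one.
    """

    phi_O: float
    phi_I: float
    phi_W: float
    oil_label: str = ""
    surfactant_label: str = ""

    def __post_init__(self):
        for name, v, lo in (("phi_O", self.phi_O, 0.0), ("phi_W", self.phi_W, 0.0)):
            if not 0.0 < v < 1.0:
                raise CompositionError(f"{name} = {v} must be in (0, 1)")
        if not 0.0 <= self.phi_I < 1.0:
            raise CompositionError(f"phi_I = {self.phi_I} must be in [0, 1)")
        total = self.phi_O + self.phi_I + self.phi_W
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"fractions sum to {total!r}, not 1")


@dataclass(frozen=True)
class PartitionSet:
    """Partition constants between emulsion regions.

    ``P_O_I`` (oil <-> interface) is always required; ``P_W_I``
    (water <-> interface) and ``P_W_O`` (water <-> oil) are optional. For a
    consistent set, P_W^O = P_W^I / P_O^I — checked by
    :func:`partition_consistency`.
    """

    P_O_I: float
    P_W_I: float | None = None
    P_W_O: float | None = None

    def __post_init__(self):
        if not self.P_O_I > 0:
            raise ValueError("P_O_I must be positive")
        for name, v in (("P_W_I", self.P_W_I), ("P_W_O", self.P_W_O)):
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when supplied")


@dataclass(frozen=True)
class KineticSeries:
    """Observed rate constants across surfactant levels at fixed [AO_T] and pH.

    ``observations`` is a sequence of (phi_I, phi_O, k_obs) or
    (phi_I, phi_O, k_obs, sd) tuples; replicate observations at the same
    phi_I are allowed and all enter the fit. At least 3 distinct phi_I
    levels are required to determine the two model parameters with a
    residual degree of freedom.
    """

    observations: tuple
    AO_T: float  # mol per liter of total emulsion
    pH: float | None = None
    antioxidant_label: str = ""
    oil_label: str = ""

    def __post_init__(self):
        obs = tuple(tuple(float(x) for x in o) for o in self.observations)
        if any(len(o) not in (3, 4) for o in obs):
            raise ValueError("observations must be (phi_I, phi_O, k_obs[, sd]) tuples")
        if not self.AO_T > 0:
            raise ValueError("AO_T must be positive")
        if any(o[2] <= 0 for o in obs):
            raise ValueError("all k_obs must be positive")
        if len({o[0] for o in obs}) < 3:
            raise InsufficientDesignError(
                "need at least 3 distinct phi_I levels to fit the model"
            )
        object.__setattr__(self, "observations", obs)

    @property
    def phi_I(self) -> np.ndarray:
        return np.array([o[0] for o in self.observations])

    @property
    def phi_O(self) -> np.ndarray:
        return np.array([o[1] for o in self.observations])

    @property
    def k_obs(self) -> np.ndarray:
        return np.array([o[2] for o in self.observations])


@dataclass(frozen=True)
class PKMFit:
    """Fitted pseudophase-model parameters with linear-fit diagnostics.

    ``slope`` and ``intercept`` are those of the 1/k_obs vs Phi_I line (in
    seconds); k_I is in M^-1 s^-1 with the antioxidant concentration
    expressed per liter of interfacial region; standard errors are
    first-order (delta-method) propagations of the OLS covariance.
    """

    P_O_I: float
    k_I: float
    slope: float  # s
    intercept: float  # s
    r_squared: float
    se_P: float
    se_kI: float
    method: str  # "reciprocal" | "nonlinear"

    def __post_init__(self):
        if not (self.P_O_I > 0 and self.k_I > 0):
            raise ValueError("fitted P_O_I and k_I must be positive")


def kobs_forward(
    partition: PartitionSet | float,
    comp: EmulsionComposition,
    AO_T: float,
    k_I: float,
) -> float:
    """Predict the observed rate constant from the two-region rate law.

    k_obs = AO_T * k_I * P_O^I / (Phi_I * P_O^I + Phi_O). Equivalently,
    k_I times the effective interfacial antioxidant concentration. For
    Phi_I = 0 (binary system) the expression reduces to AO_T * k_I * P_O^I
    / Phi_O as the limit of complete oil residence.
    """
    P = partition.P_O_I if isinstance(partition, PartitionSet) else float(partition)
    if not P > 0:
        raise ValueError("P_O_I must be positive")
    denom = comp.phi_I * P + comp.phi_O
    if denom == 0.0:
        raise CompositionError("phi_I * P_O_I + phi_O = 0: composition undefined")
    return AO_T * k_I * P / denom


def _ols_line(x: np.ndarray, y: np.ndarray):
    """OLS y = a + b x returning (intercept, slope, cov2x2, r_squared).

    The covariance is the HC3 heteroscedasticity-robust estimate: the
    reciprocal transform turns multiplicative noise on k_obs into residual
    variance proportional to (1/k_obs)^2, so the homoscedastic formula
    understates the slope/intercept uncertainty at the large-1/k end.
    On exact (zero-residual) data HC3 reduces to the zero matrix.
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    XtXinv = np.linalg.inv(X.T @ X)
    beta = XtXinv @ X.T @ y
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    leverage = np.einsum("ij,jk,ik->i", X, XtXinv, X)
    w = resid**2 / (1.0 - leverage) ** 2
    cov = XtXinv @ (X.T * w) @ X @ XtXinv
    return float(beta[0]), float(beta[1]), cov, r2


def fit_reciprocal(series: KineticSeries, phi_O_policy: str = "constant") -> PKMFit:
    """Estimate P_O^I and k_I from the reciprocal linearization.

    Unweighted OLS of 1/k_obs on Phi_I; then k_I = 1/(slope * AO_T) and
    P_O^I = Phi_O * slope / intercept. Standard errors are propagated from
    the OLS slope/intercept covariance by the delta method.

    Parameters
    ----------
    series:
        The kinetic observations (>= 3 distinct phi_I levels).
    phi_O_policy:
        ``"constant"`` (default) requires a single oil fraction across the
        series, as when surfactant is added at fixed nominal oil loading;
        ``"per-observation"`` regresses 1/k_obs on both Phi_I and Phi_O
        through the origin for volume-renormalized designs.

    Raises
    ------
    ModelMisfitError
        If the fitted slope or intercept is non-positive — the model
        requires plots of 1/k_obs vs Phi_I to be lines with positive
        intercepts.
    """
    phi_I = series.phi_I
    phi_O = series.phi_O
    y = 1.0 / series.k_obs

    if phi_O_policy == "constant":
        if not np.allclose(phi_O, phi_O[0], rtol=0, atol=1e-12):
            raise ValueError("constant phi_O policy requires equal phi_O values")
        phi_O_c = float(phi_O[0])
        intercept, slope, cov, r2 = _ols_line(phi_I, y)
        if slope <= 0:
            raise ModelMisfitError(f"slope {slope:.3g} s <= 0: data do not follow the model")
        if intercept <= 0:
            raise ModelMisfitError(
                f"intercept {intercept:.3g} s <= 0: the model requires positive intercepts"
            )
        k_I = 1.0 / (slope * series.AO_T)
        P = phi_O_c * slope / intercept
        var_i, var_s = cov[0, 0], cov[1, 1]
        cov_is = cov[0, 1]
        se_kI = np.sqrt(var_s) / (slope**2 * series.AO_T)
        # P = phi_O * s / i; grad = (dP/di, dP/ds)
        g = np.array([-phi_O_c * slope / intercept**2, phi_O_c / intercept])
        se_P = float(np.sqrt(g @ cov @ g))
        return PKMFit(
            P_O_I=P, k_I=k_I, slope=slope, intercept=intercept,
            r_squared=r2, se_P=se_P, se_kI=float(se_kI), method="reciprocal",
        )

    if phi_O_policy == "per-observation":
        # 1/k_obs = c1 * phi_I + c2 * phi_O with c1 = 1/(k_I AO_T),
        # c2 = 1/(k_I AO_T P); no intercept term in the model.
        X = np.column_stack([phi_I, phi_O])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        c1, c2 = float(beta[0]), float(beta[1])
        if c1 <= 0 or c2 <= 0:
            raise ModelMisfitError("per-observation fit gave non-positive coefficients")
        resid = y - X @ beta
        dof = max(y.size - 2, 1)
        cov = float(np.sum(resid**2)) / dof * np.linalg.inv(X.T @ X)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        k_I = 1.0 / (c1 * series.AO_T)
        P = c1 / c2
        se_kI = float(np.sqrt(cov[0, 0])) / (c1**2 * series.AO_T)
        g = np.array([1.0 / c2, -c1 / c2**2])
        se_P = float(np.sqrt(g @ cov @ g))
        mean_phi_O = float(phi_O.mean())
        return PKMFit(
            P_O_I=P, k_I=k_I, slope=c1, intercept=c2 * mean_phi_O,
            r_squared=r2, se_P=se_P, se_kI=se_kI, method="reciprocal",
        )

    raise ValueError(f"unknown phi_O_policy {phi_O_policy!r}")


def fit_nonlinear(series: KineticSeries) -> PKMFit:
    """Least-squares fit of the untransformed rate law.

    Statistically preferable to the reciprocal fit when the noise is
    additive or multiplicative in k_obs (the reciprocal transform inflates
    the noise of small rate constants). Initial values come from
    :func:`fit_reciprocal`; on non-convergence the raised error carries the
    reciprocal fit as ``fallback``.
    """
    recip = fit_reciprocal(series)
    phi_I = series.phi_I
    phi_O = series.phi_O
    k = series.k_obs
    AO_T = series.AO_T

    def model(phi, P, k_I):
        return AO_T * k_I * P / (phi * P + phi_O)

    try:
        popt, pcov = optimize.curve_fit(
            model, phi_I, k, p0=[recip.P_O_I, recip.k_I],
            maxfev=20000, xtol=1e-14, ftol=1e-14,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"nonlinear fit did not converge: {exc}", fallback=recip
        ) from exc
    P, k_I = (float(v) for v in popt)
    if P <= 0 or k_I <= 0:
        raise FitFailureError("nonlinear fit left the parameter domain", fallback=recip)
    fitted = model(phi_I, P, k_I)
    sst = float(np.sum((k - k.mean()) ** 2))
    sse = float(np.sum((k - fitted) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    slope = 1.0 / (k_I * AO_T)
    intercept = float(phi_O[0]) * slope / P
    return PKMFit(
        P_O_I=P, k_I=k_I, slope=slope, intercept=intercept,
        r_squared=r2, se_P=float(se[0]), se_kI=float(se[1]), method="nonlinear",
    )


def partition_consistency(ps: PartitionSet, rtol: float = 1e-6) -> float:
    """Return the binary oil-water partition constant implied by a triple.

    With no surfactant, the oil-water partition constant must equal the
    ratio of the emulsion constants: P_W^O = P_W^I / P_O^I. If ``ps``
    already carries P_W_O, it is checked against the implied value at
    relative tolerance ``rtol``.
    """
    if ps.P_W_I is None:
        raise ValueError("P_W_I is required to derive P_W_O")
    implied = ps.P_W_I / ps.P_O_I
    if ps.P_W_O is not None:
        rel = abs(ps.P_W_O - implied) / implied
        if rel > rtol:
            raise ConsistencyViolationError(
                f"supplied P_W_O = {ps.P_W_O:g} differs from P_W_I/P_O_I = "
                f"{implied:g} by relative {rel:.3g} (tolerance {rtol:g})"
            )
    return implied
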