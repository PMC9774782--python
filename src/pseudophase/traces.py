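"""Pseudo-first-order rate constants from absorbance-vs-time traces.

The derivatization assay quenches the probe reaction at sampled times and
reads the remaining probe as an azo-dye absorbance, so an intact-emulsion
kinetic run arrives as a decaying absorbance trace

    A_t = A_inf + (A_0 - A_inf) * exp(-k_obs * t).

Under pseudo-first-order conditions ([antioxidant] >> [probe]) the decay
constant k_obs is the observed rate constant fed to the pseudophase model.
Two estimators are provided: the classical linearization
ln((A_t - A_inf)/(A_0 - A_inf)) = -k_obs * t fitted by ordinary least
squares, and a three-parameter nonlinear exponential fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateTraceError, FitFailureError, LogDomainError

__all__ = ["AbsorbanceTrace", "FirstOrderFit", "fit_first_order", "check_coverage"]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A timestamped absorbance series from the quenching assay.

    Parameters
    ----------
    times:
        Sampling times in seconds, strictly increasing, at least 5 points.
    absorbances:
        Absorbance in AU at each time; finite and non-negative.
    label:
        Free-text identifier (antioxidant, oil, run id).
    pH:
        Bulk aqueous-phase pH of the run, if known.
    phi_I:
        Interfacial (surfactant) volume fraction of the emulsion, if known.
    """

    times: np.ndarray
    absorbances: np.ndarray
    label: str = ""
    pH: float | None = None
    phi_I: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or t.size != a.size:
            raise ValueError("times and absorbances must be 1-D and equal length")
        if t.size < 5:
            raise ValueError(f"need at least 5 points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("absorbances must be finite and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class FirstOrderFit:
    """Result of a first-order decay fit.

    ``halflives_covered`` is duration * k_obs / ln 2, the number of
    half-lives spanned by the trace — runs should cover 2-3 half-lives for
    the plateau to be well defined.
    """

    k_obs: float  # s^-1
    A0: float  # AU
    Ainf: float  # AU
    r_squared: float
    residual_sd: float  # AU, in absorbance space
    n_points: int
    halflives_covered: float
    mode: str = "linearized"

    def __post_init__(self):
        if not self.k_obs > 0:
            raise ValueError("k_obs must be positive")


def _noise_floor(absorbances: np.ndarray) -> float:
    # Second differences annihilate linear trend; for a smooth decay they
    # carry only curvature + noise, giving a conservative noise estimate.
    if absorbances.size < 3:
        return 0.0
    return float(np.std(np.diff(absorbances, n=2), ddof=0) / math.sqrt(6.0))


def fit_first_order(
    trace: AbsorbanceTrace,
    mode: str = "linearized",
    Ainf: float | None = None,
) -> FirstOrderFit:
    """Fit the integrated first-order rate law to an absorbance trace.

    Parameters
    ----------
    trace:
        The absorbance series; at least 5 points.
    mode:
        ``"linearized"`` regresses ln((A_t - Ainf)/(A0 - Ainf)) on t by OLS
        (slope = -k_obs); ``"nonlinear"`` fits
        A_t = Ainf + (A0 - Ainf) exp(-k_obs t) with all three parameters
        free (Ainf fixed if supplied).
    Ainf:
        Plateau absorbance in AU. In linearized mode, when omitted the last
        observed point is used as the plateau estimate and excluded from the
        regression.

    Returns
    -------
    FirstOrderFit

    Raises
    ------
    DegenerateTraceError
        If the amplitude |A0 - Ainf| is not resolvable above the noise.
    LogDomainError
        If any normalized amplitude is <= 0 in linearized mode; the error
        names the offending point (usually a wrong Ainf).
    """
    t = trace.times
    a = trace.absorbances
    noise = _noise_floor(a)

    if mode == "linearized":
        if Ainf is None:
            ainf = float(a[-1])
            t_fit, a_fit = t[:-1], a[:-1]
        else:
            ainf = float(Ainf)
            t_fit, a_fit = t, a
        a0 = float(a_fit[0])
        amplitude = a0 - ainf
        if abs(amplitude) <= max(10.0 * noise, 1e-12):
            raise DegenerateTraceError(
                f"|A0 - Ainf| = {abs(amplitude):.3g} AU is within 10x the "
                f"noise floor ({noise:.3g} AU); no resolvable decay"
            )
        z = (a_fit - ainf) / amplitude
        bad = np.flatnonzero(z <= 0)
        if bad.size:
            i = int(bad[0])
            raise LogDomainError(
                f"normalized amplitude <= 0 at point {i} (t = {t_fit[i]:g} s, "
                f"A = {a_fit[i]:g} AU); check the Ainf estimate",
                index=i,
            )
        y = np.log(z)
        res = stats.linregress(t_fit, y)
        k = -float(res.slope)
        if k <= 0:
            raise FitFailureError("fitted rate constant is non-positive (rising trace?)")
        fitted = ainf + amplitude * np.exp(res.intercept - k * t_fit)
        resid = a_fit - fitted
        dof = max(t_fit.size - 2, 1)
        return FirstOrderFit(
            k_obs=k,
            A0=a0,
            Ainf=ainf,
            r_squared=float(res.rvalue**2),
            residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
            n_points=int(t_fit.size),
            halflives_covered=trace.duration * k / _LN2,
            mode="linearized",
        )

    if mode == "nonlinear":
        ainf_guess = float(a[-1]) if Ainf is None else float(Ainf)
        a0_guess = float(a[0])
        amplitude = a0_guess - ainf_guess
        if abs(amplitude) <= max(10.0 * noise, 1e-12):
            raise DegenerateTraceError(
                f"|A0 - Ainf| = {abs(amplitude):.3g} AU is within 10x the "
                f"noise floor ({noise:.3g} AU); no resolvable decay"
            )
        k0 = 2.0 * _LN2 / trace.duration  # assume ~2 half-lives covered
        t0 = t - t[0]
        try:
            if Ainf is None:

                def model(tt, ainf_p, amp, k):
                    return ainf_p + amp * np.exp(-k * tt)

                popt, pcov = optimize.curve_fit(
                    model, t0, a, p0=[ainf_guess, amplitude, k0],
                    maxfev=10000, xtol=1e-14, ftol=1e-14,
                )
                ainf_fit, amp_fit, k = (float(v) for v in popt)
            else:

                def model(tt, amp, k):
                    return ainf_guess + amp * np.exp(-k * tt)

                popt, pcov = optimize.curve_fit(
                    model, t0, a, p0=[amplitude, k0],
                    maxfev=10000, xtol=1e-14, ftol=1e-14,
                )
                amp_fit, k = (float(v) for v in popt)
                ainf_fit = ainf_guess
        except RuntimeError as exc:
            raise FitFailureError(f"nonlinear fit did not converge: {exc}") from exc
        if k <= 0:
            raise FitFailureError("fitted rate constant is non-positive")
        fitted = ainf_fit + amp_fit * np.exp(-k * t0)
        resid = a - fitted
        sst = float(np.sum((a - a.mean()) ** 2))
        sse = float(np.sum(resid**2))
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        dof = max(a.size - (3 if Ainf is None else 2), 1)
        return FirstOrderFit(
            k_obs=k,
            A0=ainf_fit + amp_fit,
            Ainf=ainf_fit,
            r_squared=max(min(r2, 1.0), 0.0),
            residual_sd=float(np.sqrt(sse / dof)),
            n_points=int(a.size),
            halflives_covered=trace.duration * k / _LN2,
            mode="nonlinear",
        )

    raise ValueError(f"unknown mode {mode!r}; use 'linearized' or 'nonlinear'")


def check_coverage(fit: FirstOrderFit, min_halflives: float = 2.0) -> bool:
    """True iff the trace spans at least ``min_halflives`` half-lives.

    Kinetic runs should cover 2-3 half-lives so the plateau (and hence
    k_obs) is well determined; shorter runs pass through here flagged False.
    The comparison is inclusive: exactly ``min_halflives`` passes.
    """
    return fit.halflives_covered >= min_halflives
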