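"""Replicate aggregation with Dixon's Q-test outlier screening.

Kinetic runs are made in duplicate or triplicate; before averaging, the
single most extreme replicate is screened with Dixon's Q-test
(Q = gap/range, the r10 statistic) against the two-sided Dean-Dixon
critical values as re-tabulated by Rorabacher (n = 3-10; 90/95/99%
confidence). At most one value is ever rejected: repeated application of
the test to the same set is statistically invalid.

A precision flag marks aggregates whose coefficient of variation exceeds
9%, the upper edge of the assay's expected replicate precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientReplicatesError, ZeroRangeError

__all__ = ["ReplicateSet", "dixon_q", "aggregate", "CV_FLAG_PERCENT"]

# Two-sided r10 critical values, n = 3..10.
_Q_CRITICAL = {
    0.90: (0.941, 0.765, 0.642, 0.560, 0.507, 0.468, 0.437, 0.412),
    0.95: (0.970, 0.829, 0.710, 0.625, 0.568, 0.526, 0.493, 0.466),
    0.99: (0.994, 0.926, 0.821, 0.740, 0.680, 0.634, 0.598, 0.568),
}

CV_FLAG_PERCENT = 9.0


@dataclass(frozen=True)
class ReplicateSet:
    """Aggregated replicate rate constants.

    ``values`` are the input replicates in original order; ``rejected_index``
    points into them if Dixon's Q-test discarded one. ``mean``, ``sd`` (sample
    standard deviation, n-1 denominator) and ``cv_percent`` are computed on
    the retained values only. ``precision_flag`` is set when the CV exceeds
    the assay's 9% precision envelope.
    """

    values: tuple
    q_confidence: float
    q_statistic: float | None
    rejected_index: int | None
    mean: float
    sd: float
    cv_percent: float
    precision_flag: bool

    @property
    def retained(self) -> tuple:
        if self.rejected_index is None:
            return self.values
        return tuple(v for i, v in enumerate(self.values) if i != self.rejected_index)


def dixon_q(values, confidence: float = 0.95):
    """Dixon's Q-test (r10) for a single outlier in a small replicate set.

    Parameters
    ----------
    values:
        3 to 10 replicate values, not all equal.
    confidence:
        One of 0.90, 0.95, 0.99 (two-sided critical values).

    Returns
    -------
    (Q, rejected_index):
        Q is gap/range for the most extreme value; ``rejected_index`` is its
        position in ``values`` if Q exceeds the critical value, else None.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise InsufficientReplicatesError(f"Dixon's Q-test needs n >= 3, got {n}")
    if n > 10:
        raise ValueError(f"r10 critical values cover n <= 10, got {n}")
    if confidence not in _Q_CRITICAL:
        raise ValueError(f"confidence must be one of {sorted(_Q_CRITICAL)}")
    rng = float(x.max() - x.min())
    if rng == 0.0:
        raise ZeroRangeError("all replicate values are equal; Q is undefined")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    q_low = float(xs[1] - xs[0]) / rng
    q_high = float(xs[-1] - xs[-2]) / rng
    if q_high >= q_low:
        q, extreme = q_high, int(order[-1])
    else:
        q, extreme = q_low, int(order[0])

    critical = _Q_CRITICAL[confidence][n - 3]
    rejected = extreme if q > critical else None
    return q, rejected


def aggregate(values, confidence: float = 0.95) -> ReplicateSet:
    """Screen replicates with Dixon's Q-test (once), then average.

    For n = 2 no outlier test is possible and both values are retained.
    For n >= 3 the Q-test is applied a single time at the stated confidence.
    Mean, sample sd, and CV are computed on the retained values; the
    precision flag is set when CV > 9%.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientReplicatesError(f"need at least 2 replicates, got {n}")

    q_stat: float | None = None
    rejected: int | None = None
    if n >= 3:
        q_stat, rejected = dixon_q(x, confidence=confidence)

    retained = x if rejected is None else np.delete(x, rejected)
    mean = float(retained.mean())
    sd = float(retained.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("inf")
    return ReplicateSet(
        values=tuple(float(v) for v in x),
        q_confidence=confidence,
        q_statistic=q_stat,
        rejected_index=rejected,
        mean=mean,
        sd=sd,
        cv_percent=cv,
        precision_flag=cv > CV_FLAG_PERCENT,
    )
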