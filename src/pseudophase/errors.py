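"""Exception hierarchy for the pseudophase kinetics toolkit.

All errors derive from :class:`PseudophaseError` so callers can catch the
package's failures with a single except clause while still distinguishing
kinetic-fit problems from composition or replicate-screening problems.
"""


class PseudophaseError(ValueError):
    """Base class for all errors raised by this package."""


class DegenerateTraceError(PseudophaseError):
    """Absorbance trace has no resolvable amplitude (|A0 - Ainf| within noise)."""


class LogDomainError(PseudophaseError):
    """A normalized amplitude (A_t - Ainf)/(A0 - Ainf) is <= 0 in linearized fitting.

    Carries ``index``, the position of the offending point, which usually
    signals a wrong plateau estimate Ainf rather than bad data.
    """

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


class InsufficientReplicatesError(PseudophaseError):
    """Fewer replicates than the operation requires."""


class ZeroRangeError(PseudophaseError):
    """All replicate values identical; Dixon's Q statistic is undefined."""


class InsufficientDesignError(PseudophaseError):
    """Too few distinct design points (surfactant levels, pH levels) to fit."""


class ModelMisfitError(PseudophaseError):
    """The fitted line violates the model's sign constraints.

    The two-region pseudophase rate law requires a positive slope and a
    positive intercept of 1/k_obs vs Phi_I; anything else means the data do
    not follow the model (or the design is degenerate).
    """


class FitFailureError(PseudophaseError):
    """Iterative fit failed to converge.

    ``fallback`` carries the linearized fit so callers can still proceed.
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class ConsistencyViolationError(PseudophaseError):
    """A supplied partition-constant triple violates P_W^O = P_W^I / P_O^I."""


class CompositionError(PseudophaseError):
    """Emulsion volume fractions are invalid or do not close to one."""


class UndefinedConcentrationError(PseudophaseError):
    """Effective concentration requested for a region of zero volume."""
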