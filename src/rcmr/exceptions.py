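"""Package-wide exception types.

Every failure mode the pipeline reports explicitly (rather than silently
propagating a numerical artifact) has its own class so callers can branch on
it: unattainable outcome prevalence, monomorphic variants, perfect separation
or non-convergence in logistic fits, empty instrument sets after the
pleiotropy exclusion rule, and unharmonizable variant pairs.
"""


class RcmrError(Exception):
    """Base class for all rcmr errors."""


class SimulationError(RcmrError):
    """Invalid simulation configuration or unattainable generative target."""


class PrevalenceError(SimulationError):
    """Bisection for the binary-outcome intercept could not bracket the target."""


class MonomorphicVariantError(RcmrError):
    """A variant with no allelic variation was passed to an association fit."""


class ConvergenceError(RcmrError):
    """A likelihood fit failed to converge or encountered perfect separation."""


class WeakInstrumentError(RcmrError):
    """Instrument-on-exposure effect too close to zero for Wald scaling."""


class EmptyInstrumentSetError(RcmrError):
    """No variant survived instrument selection/exclusion for a direction."""


class HarmonizationError(RcmrError):
    """Exposure and outcome association records could not be allele-matched."""
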