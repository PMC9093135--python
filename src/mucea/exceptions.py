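"""Exception hierarchy for the pipeline."""


class MuceaError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MuceaError, ValueError):
    """An argument violates an operation's preconditions."""


class ReconstructionInfeasibleError(MuceaError):
    """The risk table cannot be reconciled with the digitized curve.

    Raised when the events implied by the curve drops exceed the number of
    subjects available in an inter-risk-table interval.
    """

    def __init__(self, interval_index, interval, message=None):
        self.interval_index = interval_index
        self.interval = interval
        msg = message or (
            f"reconstruction infeasible in interval {interval_index} "
            f"[{interval[0]:g}, {interval[1]:g}): implied events exceed "
            f"subjects at risk"
        )
        super().__init__(msg)


class NonIdentifiableError(MuceaError):
    """The survival likelihood has no interior maximum (e.g. zero events)."""


class FitFailureError(MuceaError):
    """The optimizer failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ModelConstructionError(MuceaError):
    """A transition probability left [0, 1] while building the Markov model."""


class ConfigurationError(MuceaError):
    """The economic configuration is incomplete or inconsistent."""
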