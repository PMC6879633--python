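"""Exception hierarchy for confex."""


class ConfexError(Exception):
    """Base class for all confex errors."""


class InsufficientDataError(ConfexError):
    """Too few data points for the requested fit."""


class NoPeakError(ConfexError):
    """No signal above baseline at a requested peak seed."""


class NoTransitionError(ConfexError):
    """A denaturation curve shows no detectable folding transition."""


class ConvergenceError(ConfexError):
    """A nonlinear fit failed to converge."""


class InvalidModelError(ConfexError):
    """Model parameters violate their invariants (e.g. a bad rate matrix)."""
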