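"""Exception and warning types shared across the package."""


class InvalidInputError(ValueError):
    """An argument violates an operation's precondition."""


class InvariantError(ValueError):
    """A domain object violates one of its structural invariants."""


class FitImpossibleError(InvalidInputError):
    """Likelihood fitting was requested on data that cannot support it
    (e.g. no uncensored events)."""


class ConvergenceError(RuntimeError):
    """The optimiser failed to converge; the message carries diagnostics."""


class ParamSpecError(InvalidInputError):
    """A sensitivity-analysis parameter specification is infeasible; the
    message names the offending parameter."""


class ValidationError(InvalidInputError):
    """A file failed schema validation; the message names field and row."""


class CalibrationBoundaryWarning(UserWarning):
    """Calibration found no interior optimum; the boundary value was
    returned."""
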