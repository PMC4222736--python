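"""Exception hierarchy."""


class MplvError(Exception):
    """Base class for all package errors."""


class SchemaError(MplvError):
    """A CSV/config file does not match the documented schema."""


class ParseError(MplvError):
    """A cell could not be parsed; carries the offending row."""


class ValidationError(MplvError, ValueError):
    """A domain-type invariant is violated."""


class DomainError(MplvError, ValueError):
    """An operation was called outside its domain of validity."""


class FixtureLookupError(MplvError, KeyError):
    """Unknown packaged-fixture name."""

    def __init__(self, name: str, valid: tuple[str, ...]):
        super().__init__(
            f"unknown fixture {name!r}; valid names: {', '.join(sorted(valid))}"
        )
        self.name = name
        self.valid = valid


class NumericalError(MplvError, ArithmeticError):
    """Time integration produced a non-finite state."""

    def __init__(self, message: str, time_reached: float | None = None):
        super().__init__(message)
        self.time_reached = time_reached


class CalibrationError(MplvError, RuntimeError):
    """Surrogate calibration could not be performed or did not converge."""

    def __init__(self, message: str, best_params=None, residuals=None):
        super().__init__(message)
        self.best_params = best_params
        self.residuals = residuals
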