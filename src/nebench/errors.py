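"""Exception hierarchy shared by all nebench modules.

Exit-code mapping used by the CLI: configuration problems (2), data/format
problems (3), runtime failures such as deme extinction (4).
"""


class NebenchError(Exception):
    """Base class for all package errors."""


class ConfigError(NebenchError):
    """Invalid configuration value or schema violation."""


class ValidationError(ConfigError):
    """Domain-object invariant violated (e.g. survival outside [0, 1])."""


class UndefinedGenerationError(ValidationError):
    """All fertility weights are zero: generation length is undefined."""


class FormatError(NebenchError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class PedigreeIntegrityError(NebenchError):
    """A non-founder individual is missing a parent record."""


class ExtinctionError(NebenchError):
    """A deme ran out of mature individuals of one sex."""

    def __init__(self, deme: int, step: int, sex: str):
        super().__init__(
            f"deme {deme} has no mature {sex} individuals at step {step}"
        )
        self.deme = deme
        self.step = step
        self.sex = sex


class ShortfallError(NebenchError):
    """Fewer eligible loci or individuals than requested."""

    def __init__(self, what: str, requested: int, available: int):
        super().__init__(
            f"requested {requested} {what} but only {available} are eligible"
        )
        self.what = what
        self.requested = requested
        self.available = available


class IncompleteLifetimeError(NebenchError):
    """Cohort truncated by the end of the simulation."""
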