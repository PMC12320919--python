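"""Exception hierarchy for lipgain.

All library errors derive from :class:`LipgainError` so callers (and the CLI)
can catch one base class.  Validation errors double as ``ValueError`` and
numerical faults as ``RuntimeError`` to stay idiomatic.
"""


class LipgainError(Exception):
    """Base class for all lipgain errors."""


class InvalidSpecError(LipgainError, ValueError):
    """A saccade/trial specification violates its invariants."""


class InvalidParameterError(LipgainError, ValueError):
    """A signal or model parameter is outside its valid domain."""


class OutOfRangeError(LipgainError, ValueError):
    """A position falls outside the modelled visual space."""


class ConfigError(LipgainError, ValueError):
    """A configuration file is schema-invalid (unknown or ill-typed keys)."""


class NumericalFaultError(LipgainError, RuntimeError):
    """A drive contained NaN/Inf; carries the offending population id."""

    def __init__(self, population: str, message: str = ""):
        self.population = population
        super().__init__(message or f"non-finite drive in population '{population}'")


class InstabilityError(LipgainError, RuntimeError):
    """Rates exceeded the configured ceiling; carries the offending step."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"rate ceiling exceeded at integration step {step}")


class LayoutError(LipgainError, ValueError):
    """Decoder weights and a recording disagree on the input layout."""


class EmptyDatasetError(LipgainError, ValueError):
    """A temporal offset left no valid (input, target) pairs."""


class InvalidWindowError(LipgainError, ValueError):
    """A GFI steady window overlaps the saccade or the PC-delay span."""


class DegenerateSteadyStateError(LipgainError, ValueError):
    """Pre- and post-saccadic steady rates coincide; the GFI is undefined.

    Selection code treats this as "exclude the neuron", never as a crash.
    """
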