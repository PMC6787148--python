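"""Exception hierarchy shared across the package."""


class ActifractalError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ActifractalError, ValueError):
    """A parameter is outside its documented domain."""


class InputError(ActifractalError, ValueError):
    """An input series or file is malformed or too short."""


class DegenerateSeriesError(ActifractalError, ValueError):
    """The requested statistic is undefined for this input (e.g. constant series)."""


class InsufficientDataError(ActifractalError, ValueError):
    """Not enough observations to carry out the requested fit or aggregation."""


class GenerationError(ActifractalError, RuntimeError):
    """A synthetic realization violated its own construction invariants."""


class ConvergenceError(ActifractalError, RuntimeError):
    """A numerical optimizer failed to converge; the message carries the last iterate."""
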