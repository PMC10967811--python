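"""Exception hierarchy.

Every error class carries a distinct process exit code so the CLI can
map failure modes to shell-observable statuses (0 = success, 2 = usage,
3+ = the classes below).
"""


class RhinoflowError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidParameterError(RhinoflowError, ValueError):
    """A physical parameter violates its domain (e.g. Dh <= 0)."""

    exit_code = 3


class UndefinedFrictionError(RhinoflowError, ValueError):
    """Friction factor requested at a Reynolds number where it diverges."""

    exit_code = 4


class SamplingResolutionError(RhinoflowError, ValueError):
    """Time series sampled too coarsely for the requested operation."""

    exit_code = 5


class WidthUndefinedError(RhinoflowError, ValueError):
    """Hysteresis width undefined (no zero-flow crossing in the data)."""

    exit_code = 6


class DegenerateInputError(RhinoflowError, ValueError):
    """Input carries no information for the requested fit or measure."""

    exit_code = 7


class FitFailureError(RhinoflowError, RuntimeError):
    """Optimizer failed to converge within its evaluation budget."""

    exit_code = 8


class SchemaError(RhinoflowError, ValueError):
    """A CSV or config file does not match the documented schema."""

    exit_code = 9


class OrderingError(RhinoflowError, ValueError):
    """Time stamps are not strictly increasing within a series."""

    exit_code = 10


class LabellingError(RhinoflowError, ValueError):
    """Required side/phase labels are missing or inconsistent."""

    exit_code = 11


class ExtrapolationError(RhinoflowError, ValueError):
    """Query point lies outside the sampled range."""

    exit_code = 12


class UndefinedResistanceError(RhinoflowError, ValueError):
    """Resistance requested at zero flow."""

    exit_code = 13


class ScalesUndefinedError(RhinoflowError, ValueError):
    """Kolmogorov scales requested for non-dissipating (laminar) input."""

    exit_code = 14


class EmptyReportError(RhinoflowError, ValueError):
    """Resolution report requested for an empty cell population."""

    exit_code = 15
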