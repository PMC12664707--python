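"""Exception hierarchy and warnings."""


class SrsMetricsError(Exception):
    """Base class for all srsmetrics errors."""


class LatticeMismatchError(SrsMetricsError):
    """Two objects that must share a voxel lattice do not."""


class DegenerateStructureError(SrsMetricsError):
    """A structure mask is empty (or became empty, e.g. after contraction)."""


class DegeneratePlanError(SrsMetricsError):
    """A plan-level quantity is undefined (e.g. zero prescription isodose volume)."""


class DomainError(SrsMetricsError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ExtentError(SrsMetricsError):
    """A phantom grid is too small to contain the required isodose volume."""


class ValidationError(SrsMetricsError):
    """An input document is structurally invalid; lists the offending fields."""

    def __init__(self, message, fields=()):
        super().__init__(message)
        self.fields = tuple(fields)


class TruncationWarning(UserWarning):
    """An isodose volume is clipped by the grid boundary; the metric is a lower bound."""
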