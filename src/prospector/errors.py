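"""Exception hierarchy shared across the package."""


class ProspectorError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ProspectorError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedMetricError(ProspectorError):
    """A metric is requested on a degenerate mask (no positives or no negatives)."""


class FeasibilityError(ProspectorError):
    """Region planting could not satisfy the component constraints."""


class FitError(ProspectorError):
    """Model fitting failed on a degenerate design."""
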