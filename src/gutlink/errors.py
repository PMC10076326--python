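"""Exception types shared across the package."""


class GutlinkError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(GutlinkError, ValueError):
    """A cohort or run configuration violates its invariants."""


class InputError(GutlinkError, ValueError):
    """Malformed input data (lengths, ranges, parse problems)."""


class UndefinedCorrelationError(GutlinkError, ValueError):
    """Correlation requested on a zero-variance sequence.

    Callers decide whether to exclude the offending gene/taxon or fail.
    """


class DegenerateFitError(GutlinkError, ValueError):
    """A model fit has no residual variance where the test requires one."""


class UnsupportedLayoutError(GutlinkError, ValueError):
    """Factorial layout with empty cells, which the ANOVA does not support."""


class DependencyError(GutlinkError, RuntimeError):
    """A pipeline stage was invoked before the stages it depends on."""
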