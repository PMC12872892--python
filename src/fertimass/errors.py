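"""Exception hierarchy shared across the package."""


class FertimassError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FertimassError, ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(InvalidInputError):
    """Input is structurally valid but statistically degenerate
    (e.g. a sample with zero variance handed to a variance-based test)."""


class UnbalancedDesignError(InvalidInputError):
    """A repeated-measures layout is incomplete or unbalanced.

    The balanced closed forms used here require every subject x time cell
    exactly once; incomplete data must be handled (listwise) upstream.
    """


class SchemaError(FertimassError, ValueError):
    """A file does not match the expected tabular schema."""


class ConfigError(FertimassError, ValueError):
    """A simulation or pipeline configuration is inconsistent."""
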