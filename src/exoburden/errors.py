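"""Exception hierarchy for the exoburden pipeline."""


class ExoburdenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ExoburdenError):
    """Invalid simulation or pipeline configuration."""


class FormatError(ExoburdenError):
    """Malformed genotype file (bad magic number, truncated payload, dimension mismatch)."""


class SchemaError(ExoburdenError):
    """Tabular input is missing a required column."""


class ValidationError(ExoburdenError):
    """Input values violate a domain constraint (e.g. test score out of range)."""


class QCError(ExoburdenError):
    """Quality control cannot proceed (unknown sex with X variants, empty matrix)."""


class AnalysisError(ExoburdenError):
    """Statistical model cannot be fitted (rank deficiency, too few samples)."""
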