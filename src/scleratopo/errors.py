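"""Exception hierarchy shared across the pipeline."""


class ScleratopoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScleratopoError):
    """An input file does not match the expected dialect/schema."""


class DataError(ScleratopoError):
    """Input data are unusable (e.g. empty after filtering)."""


class ConfigurationError(ScleratopoError):
    """Invalid or inconsistent configuration."""


class FitError(ScleratopoError):
    """A least-squares fit could not be computed or did not converge."""


class OrientationError(ScleratopoError):
    """A surface normal or frame is oriented inconsistently."""


class QualityError(ScleratopoError):
    """A measurement failed a pipeline quality gate (e.g. apex at edge,
    more than half of the meridians cut away)."""
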