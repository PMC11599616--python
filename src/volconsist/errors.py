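"""Error types shared across the pipeline stages."""


class VolconsistError(ValueError):
    """Base class for all package-specific errors."""


class InsufficientDataError(VolconsistError):
    """Raised when a computation needs more rows/columns than supplied."""


class DegenerateRatingsError(VolconsistError):
    """Raised when a ratings matrix carries no usable variance (e.g. constant)."""
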