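"""Exception hierarchy shared by all stages."""


class GMRError(Exception):
    """Base class for all package errors."""


class FormatError(GMRError):
    """Malformed input file (missing column, bad GMT line, duplicate ids)."""


class ValidationError(GMRError):
    """Arguments outside their contract (lambda < 4, epsilon off-grid, ...)."""


class DataError(GMRError):
    """Data that cannot be analyzed (empty after QC, non-positive median, ...)."""
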