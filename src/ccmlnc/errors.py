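"""Exception hierarchy shared across the package."""


class CcmlncError(Exception):
    """Base class for all errors raised by ccmlnc."""


class FormatError(CcmlncError):
    """Malformed input data (bad TSV cell, GTF/GMT/BED violation, ...)."""


class ConfigError(CcmlncError):
    """Invalid configuration values or inconsistent parameter combinations."""


class AnalysisError(CcmlncError):
    """A statistical or structural precondition of an analysis step failed."""
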