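"""Exception hierarchy shared across the pipeline."""


class SigcorrError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(SigcorrError):
    """Invalid configuration or parameter contract violation."""


class MatrixFormatError(SigcorrError):
    """Malformed on-disk matrix / signature / annotation input."""


class EmptyResultError(SigcorrError):
    """An operation removed everything it was given (all cells, all genes, ...)."""


class InsufficientCellsError(SigcorrError):
    """Too few cells to evaluate a statistic."""


class DegenerateInputError(SigcorrError):
    """A statistic is undefined on this input (e.g. zero variance)."""
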