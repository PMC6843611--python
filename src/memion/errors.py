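"""Exception hierarchy shared by all analysis stages."""


class MemionError(Exception):
    """Base class for all package errors."""


class FormatError(MemionError):
    """Malformed or inconsistent input files (e.g. atom-count mismatch)."""


class ValidationError(MemionError):
    """Role-map or configuration validation failure."""


class AnalysisError(MemionError):
    """A geometric/statistical analysis cannot proceed (empty window, missing roles...)."""


class NumericalError(MemionError):
    """An iterative solver failed to converge."""


class RangeError(MemionError):
    """A fitted feature (e.g. capacitance minimum) lies outside the scanned range."""


class FitError(MemionError):
    """A least-squares fit is degenerate or unidentifiable."""


class GenerationError(MemionError):
    """Synthetic-system generation failed (e.g. lattice packing capacity exceeded)."""
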