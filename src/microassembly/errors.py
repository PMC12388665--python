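"""Exception hierarchy shared across the package."""


class MicroassemblyError(Exception):
    """Base class for package errors."""


class TableFormatError(MicroassemblyError, ValueError):
    """Malformed on-disk table (duplicate labels, bad header, non-numeric cells)."""


class ValidationError(MicroassemblyError, ValueError):
    """In-memory object violates a type invariant (negative counts, bad ranges)."""


class ParameterError(MicroassemblyError, ValueError):
    """Invalid argument to an operation (unknown rank, k >= n, bad bounds)."""


class InsufficientDataError(MicroassemblyError, ValueError):
    """Input too small for the requested statistic."""


class FitError(MicroassemblyError, RuntimeError):
    """Model fit failed or is undefined (non-convergence, zero total variance)."""
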