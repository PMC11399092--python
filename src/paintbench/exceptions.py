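"""Exception hierarchy shared across the package."""


class PaintBenchError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PaintBenchError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(PaintBenchError, ValueError):
    """A localization file or table violates the column/metadata schema."""


class DegenerateFitError(PaintBenchError, RuntimeError):
    """A fit cannot be performed on degenerate input (e.g. identical durations)."""


class InsufficientDataError(PaintBenchError, RuntimeError):
    """Not enough observations to produce a reliable estimate."""
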