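"""Package-specific error types.

Argument-contract violations raise plain :class:`ValueError`; the classes
here mark conditions a caller may want to catch selectively (malformed cube
files, degenerate data, impossible selections).
"""


class HerbscreenError(Exception):
    """Base class for all herbscreen-specific errors."""


class CubeFormatError(HerbscreenError):
    """A cube file violates the long-format CSV dialect.

    ``row`` is the 1-based line number in the file (header = line 1) when
    the violation is attributable to a single row, else ``None``.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class EmptySelectionError(HerbscreenError):
    """A crop or subset operation selected no elements."""


class DegenerateRowError(HerbscreenError):
    """A row-wise transform hit a zero-variance row; names the sample."""

    def __init__(self, sample_id: str):
        super().__init__(f"zero-variance row for sample {sample_id!r}")
        self.sample_id = sample_id


class StratificationError(HerbscreenError):
    """Cross-validation folds could not preserve class representation."""
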