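"""Exception hierarchy shared across the package."""


class PPIProfilerError(Exception):
    """Base class for all package errors."""


class RecordError(PPIProfilerError):
    """A single input record (SMILES line or SDF record) could not be processed.

    Carries the position of the offending record so callers can skip-and-log
    or abort with a useful message.
    """

    def __init__(self, message: str, index: int | None = None):
        self.index = index
        if index is not None:
            message = f"record {index}: {message}"
        super().__init__(message)


class EmbeddingError(PPIProfilerError):
    """3D conformer generation failed for a molecule."""


class DescriptorError(PPIProfilerError):
    """A descriptor could not be computed (e.g. missing coordinates)."""


class MetricError(PPIProfilerError):
    """A classification metric is undefined for the given counts."""


class DataError(PPIProfilerError):
    """Bad or missing user-supplied data (files, tables, columns)."""
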