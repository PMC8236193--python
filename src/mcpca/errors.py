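"""Exception hierarchy for the mcpca package."""


class McpcaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(McpcaError, ValueError):
    """A file or stream does not conform to its declared format."""


class DataError(McpcaError, ValueError):
    """Input data violate a precondition of an operation."""


class DegenerateTransformError(DataError):
    """A per-feature transform has zero variance on the observed categories."""
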