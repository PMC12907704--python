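"""Exception hierarchy shared across the package."""


class CfdeconvError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(CfdeconvError, ValueError):
    """Two matrices that must share probe/sample indexing do not."""


class ValidationError(CfdeconvError, ValueError):
    """An input violates a documented precondition (range, sign, shape)."""


class EmptySelectionError(CfdeconvError, ValueError):
    """A filtering step removed every probe."""


class ParseError(CfdeconvError, ValueError):
    """A text matrix file is malformed (ragged rows, duplicate IDs, ...)."""


class ModelFormatError(CfdeconvError, ValueError):
    """A serialized model file is truncated or from an unknown format version."""
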