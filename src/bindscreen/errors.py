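"""Exception hierarchy shared across the package."""


class BindscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BindscreenError, ValueError):
    """A value violates a documented precondition (non-positive rate, empty map, ...)."""


class InvalidProtocolError(BindscreenError, ValueError):
    """An injection protocol is internally inconsistent or yields an empty time grid."""


class InvalidCantileverError(BindscreenError, ValueError):
    """Cantilever metadata is missing or non-physical."""


class InvalidMetadataError(BindscreenError, ValueError):
    """A file sidecar lacks the information needed to interpret the data."""


class InsufficientDataError(BindscreenError, ValueError):
    """Too few samples, bins or curves to carry out the requested analysis."""


class UnfittableSegmentError(BindscreenError, ValueError):
    """A data segment cannot support the requested fit (e.g. all-nonpositive decay)."""
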