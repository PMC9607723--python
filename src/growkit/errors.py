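"""Exception hierarchy."""


class GrowkitError(Exception):
    """Base class for all package errors."""


class AttachmentError(GrowkitError):
    """Invalid attachment point or failed core/R-group merge."""


class EmbeddingError(GrowkitError):
    """Distance-geometry embedding failed for every attempt."""


class CoreMismatchError(GrowkitError):
    """Maximum common substructure too small to define a shared core."""


class ReceptorError(GrowkitError):
    """Receptor loading, fixing or parameterisation failure."""


class ScoringError(GrowkitError):
    """External scorer invocation or output parsing failure."""


class ConfigError(GrowkitError):
    """Invalid workflow configuration."""
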