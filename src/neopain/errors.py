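"""Exception hierarchy shared across the package."""


class NeopainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeopainError):
    """An on-disk bundle or parameter archive is malformed."""


class ValidationError(NeopainError):
    """A value violates a documented invariant (carries the field name)."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class EmptyEpisodeError(NeopainError):
    """An episode has no modality present."""


class InsufficientDataError(NeopainError):
    """A signal is too short for the requested operation."""


class EmptyGraphError(NeopainError):
    """All concept nodes are masked; graph propagation is undefined."""


class ShapeError(NeopainError):
    """An array dimension does not match the architecture contract."""


class LeakageError(NeopainError):
    """Meta-learning task construction violates infant disjointness."""


class InsufficientBatchError(NeopainError):
    """Contrastive loss needs at least two samples to form negatives."""
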