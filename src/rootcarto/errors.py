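"""Exception types shared across the pipeline stages."""


class RootCartoError(Exception):
    """Base class for all package errors."""


class ChannelError(RootCartoError, KeyError):
    """A named channel is missing from a stack or file."""


class MetadataError(RootCartoError):
    """Required metadata (e.g. voxel size) is absent and not overridden."""


class PlacementError(RootCartoError):
    """Synthetic nuclei could not be placed without overlap."""


class AxisFitError(RootCartoError):
    """Root axis fitting failed (degenerate or insufficient point cloud)."""


class PreconditionError(RootCartoError, ValueError):
    """An operation's stated precondition is violated."""
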