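"""Exception hierarchy shared across the pipeline stages."""


class MyobeatError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MyobeatError, ValueError):
    """Invalid configuration or operation parameters."""


class InputError(MyobeatError, ValueError):
    """Unreadable, empty, or non-finite input data."""


class GeometryError(MyobeatError, ValueError):
    """Synthetic tissue geometry does not fit the requested image."""


class SegmentationFailure(MyobeatError, RuntimeError):
    """Tissue segmentation produced an empty foreground for a frame."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"segmentation failed on frame {frame_index}")


class ConsistencyError(MyobeatError, ValueError):
    """Objects from different frames were combined."""


class EmptyRegionError(MyobeatError, ValueError):
    """A regional signal was requested for a region empty in every frame."""


class InsufficientPairsError(MyobeatError, ValueError):
    """Fewer than two complete pairs available for a paired comparison."""
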