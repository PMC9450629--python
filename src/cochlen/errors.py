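"""Exception hierarchy for canal measurement failures."""


class CochlenError(Exception):
    """Base class for all package-specific errors."""


class SegmentationError(CochlenError):
    """Thresholding produced an empty foreground.

    Carries the threshold that was applied so the caller can report it.
    """

    def __init__(self, threshold: float, message: str | None = None):
        self.threshold = threshold
        super().__init__(
            message
            or f"segmentation produced empty foreground (threshold={threshold!r})"
        )


class SeedError(CochlenError):
    """A seed point lies farther than the snap radius from the skeleton."""


class ConnectivityError(CochlenError):
    """Vestibule and apex seeds fall in disconnected skeleton components.

    The software analogue of an obstructed canal.
    """


class PrefixInfeasibleError(CochlenError):
    """The curve is too short to place the mandatory chord prefix."""


class RunawayWalkError(CochlenError):
    """The chord walk exceeded the configured segment-count guard."""
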