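"""Exception hierarchy for wormtrack."""


class WormtrackError(Exception):
    """Base class for all wormtrack errors."""


class EmptyMaskError(WormtrackError):
    """An operation requiring a non-empty mask received an empty one."""


class BranchedSkeletonError(WormtrackError):
    """A clean (unbranched) skeleton was required but the mask's skeleton branches."""


class NoSeparableFrameError(WormtrackError):
    """No frame exists where every worm is separate with an unbranched skeleton."""


class NoCandidatesError(WormtrackError):
    """A worm entered the optimizer with an empty candidate list."""


class FixtureError(WormtrackError):
    """A synthetic scenario is invalid (e.g. a worm leaves the dish region)."""


class EvaluationError(WormtrackError):
    """Tracker output and ground truth cannot be compared (e.g. id mismatch)."""
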