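"""Exception hierarchy for disperseq.

Every error raised on a violated precondition derives from
:class:`DisperseqError`, so callers can catch pipeline failures uniformly.
"""


class DisperseqError(Exception):
    """Base class for all disperseq errors."""


class PackingError(DisperseqError):
    """Requested cells cannot be packed without overlap at the given radii."""


class DegenerateHistogramError(DisperseqError):
    """An ROI has too few distinct intensity values to threshold."""


class TooThinObjectError(DisperseqError):
    """Erosion annihilated the object; no cytoplasm region remains."""


class MissingBackgroundError(DisperseqError):
    """A Z plane occupied by the mask has no background voxels."""


class ZeroBackgroundError(DisperseqError):
    """A background plane mean is zero; normalization would divide by zero."""


class UndefinedOrientationError(DisperseqError):
    """A zero-length vector makes the orientation angle undefined."""


class TrackError(DisperseqError):
    """A track is too short or degenerate for the requested metric."""
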