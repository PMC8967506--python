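"""Exception hierarchy for echoseg.

All library-raised failures derive from :class:`EchosegError` so callers can
distinguish algorithmic outcomes (no chamber found, contour collapse) from
programming errors, which raise the usual built-ins.
"""

from __future__ import annotations


class EchosegError(Exception):
    """Base class for all echoseg errors."""


class InputError(EchosegError):
    """A file or image input is missing, unreadable, or malformed."""


class ParameterError(EchosegError, ValueError):
    """A parameter violates its documented domain (e.g. beta outside (0,1])."""


class DegenerateInputError(EchosegError):
    """The input is valid but degenerate for the requested operation.

    Examples: a single-gray-level histogram handed to the threshold search,
    or an all-foreground mask handed to the signed-distance transform.
    """


class InvalidThresholdError(EchosegError):
    """A candidate threshold leaves one class empty.

    Raised instead of returning a numeric entropy so that the threshold
    search can exclude (rather than silently score) degenerate splits.
    """


class ContourCollapseError(EchosegError):
    """The evolving zero level set vanished (contour shrank to nothing).

    Attributes
    ----------
    last_field : LevelSetField or None
        The last embedding that still had a zero crossing.
    """

    def __init__(self, message: str = "zero level set has collapsed", last_field=None):
        super().__init__(message)
        self.last_field = last_field


class NoChamberError(EchosegError):
    """No candidate cavity component above the minimum area was found."""
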