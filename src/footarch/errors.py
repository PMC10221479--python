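"""Exception hierarchy for the footprint-analysis pipeline.

Each exception carries the process exit code used by the command-line
interface: 1 for configuration problems, 2 for segmentation/pipeline
failures, 3 for I/O failures.
"""


class FootArchError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 2


class ConfigError(FootArchError):
    """Invalid palette, run configuration, or option values."""

    exit_code = 1


class InputError(FootArchError):
    """Missing or unreadable input path."""

    exit_code = 3


class FormatError(FootArchError):
    """Input bytes could not be decoded as an image."""

    exit_code = 3


class OutputError(FootArchError):
    """Report or image could not be written."""

    exit_code = 3


class SegmentationError(FootArchError):
    """No usable foot contour could be found."""


class BoundsError(FootArchError):
    """A bounding box lies outside its parent image."""


class DegenerateAxisError(FootArchError):
    """The two axis points coincide; no progression angle exists."""


class PeakNotFoundError(FootArchError):
    """No pixel of the maximum pressure class is present."""


class EmptyFootprintError(FootArchError):
    """A mask that must contain foreground is empty."""


class DomainError(FootArchError):
    """A scalar argument lies outside its valid domain."""


class SpecError(FootArchError):
    """A synthetic footprint specification is inconsistent."""

    exit_code = 1
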