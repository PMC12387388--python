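"""Exception hierarchy shared by the library and the command line.

Each class maps to a distinct process exit code so shell pipelines can
tell a bad parameter from a bad file from a missing calibration marker.
"""


class PlanimError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(PlanimError):
    """A parameter or input violates a documented precondition."""

    exit_code = 2


class VideoIOError(PlanimError):
    """A video file is missing, unreadable, or contains no frames."""

    exit_code = 3


class CalibrationError(PlanimError):
    """Calibration markers could not be found or measured."""

    exit_code = 4
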