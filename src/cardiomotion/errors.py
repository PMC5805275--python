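"""Exception hierarchy for cardiomotion.

Every failure mode the pipeline can report maps to one of these classes so
that callers (and the CLI exit-code table) can distinguish bad inputs from
bad parameters from degenerate data.
"""


class CardiomotionError(Exception):
    """Base class for all cardiomotion errors."""


class InputFormatError(CardiomotionError):
    """The input file or directory could not be read as a recording."""


class InsufficientDataError(CardiomotionError):
    """Fewer frames (or trace samples) than the operation requires."""


class MissingMetadataError(CardiomotionError):
    """Required acquisition metadata (frame rate) absent and not supplied."""


class BoundsError(CardiomotionError):
    """A region of interest or frame range falls outside the recording."""


class ParameterError(CardiomotionError):
    """A user-supplied parameter is out of its valid range."""


class DegenerateMaskError(CardiomotionError):
    """The noise mask is empty or undefined (no motion above noise)."""


class UndefinedScoreError(CardiomotionError):
    """A correlation score is undefined (zero-variance trace)."""


class InsufficientBeatsError(CardiomotionError):
    """Too few detected beats for the requested statistic."""
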