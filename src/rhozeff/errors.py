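"""Exception hierarchy shared across the package."""


class RhoZeffError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RhoZeffError, ValueError):
    """A precondition on user input is violated."""


class FitError(RhoZeffError):
    """A calibration or least-squares fit could not be performed."""


class InversionError(RhoZeffError):
    """A calibration curve cannot be inverted (non-monotonic)."""


class RangeError(RhoZeffError, ValueError):
    """A requested value lies outside a table or curve domain."""


class GenerationError(RhoZeffError):
    """Artificial-tissue generation failed for a specific target."""


class ConvergenceError(GenerationError):
    """An iterative adjustment hit its iteration cap."""


class AssignmentError(RhoZeffError):
    """HU-interval assignment failed (non-monotonic HU sequence)."""


class ExportError(RhoZeffError):
    """Material export failed (e.g. duplicate names)."""


class VolumeIOError(RhoZeffError, IOError):
    """Reading or writing an image volume failed."""
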