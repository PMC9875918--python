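"""Exception and warning types used across the package."""


class PrepairError(Exception):
    """Base class for all errors raised by this package."""


class DimensionMismatchError(PrepairError):
    """Array dimensions disagree with each other or with the acquisition parameters."""


class FormatError(PrepairError):
    """An input file is not in the expected format (e.g. not a 4D image)."""


class TableParseError(PrepairError):
    """A numeric table could not be parsed.

    Parameters
    ----------
    message : str
    line_number : int or None
        1-based line number of the offending row, when known.
    """

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class EmptyMaskError(PrepairError):
    """A voxel mask ended up with no voxels selected."""


class InsufficientSamplesError(PrepairError):
    """Too few time points for the requested operation."""


class NoFundamentalError(PrepairError):
    """No spectral peak survived the exclusion notches inside the search band."""


class InsufficientCyclesError(PrepairError):
    """Fewer than two oscillation peaks were found in a waveform."""


class ConfigurationError(PrepairError):
    """Inconsistent acquisition or simulation configuration."""


class PrepairWarning(UserWarning):
    """Base warning category for non-fatal conditions (empty slices, clipped bands, ...)."""
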