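"""Exception hierarchy shared across the package."""


class SongprefError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SongprefError, ValueError):
    """A parameter is outside its valid range (e.g. cutoff at/above Nyquist)."""


class EmptyInputError(SongprefError, ValueError):
    """An operation received empty audio or an empty trajectory."""


class InsufficientDataError(SongprefError, ValueError):
    """Too few observations for the requested statistic."""


class InvalidSegmentationError(SongprefError, ValueError):
    """Syllable intervals overlap, are reversed, or fall outside the clip."""


class InfeasibleAdjustmentError(SongprefError, RuntimeError):
    """Duration restoration would require a negative silent pause."""


class FormatError(SongprefError, ValueError):
    """Unsupported or corrupt file format."""


class ValidationError(SongprefError, ValueError):
    """A text input failed validation; carries file/line context."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}:"
        if line is not None:
            prefix += f"{line}:"
        super().__init__(f"{prefix} {message}" if prefix else message)
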