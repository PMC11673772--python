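"""Exception hierarchy for the faivar package."""


class FAIvarError(Exception):
    """Base class for all faivar errors."""


class InvalidInputError(FAIvarError, ValueError):
    """A function received data violating its preconditions."""


class InvalidConfigError(FAIvarError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class SequencingError(FAIvarError):
    """Frames arrived out of order; the caller must handle dropped frames."""


class MaskFormatError(FAIvarError, IOError):
    """A mask file could not be read or has an unsupported pixel format."""
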