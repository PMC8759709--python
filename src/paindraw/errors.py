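"""Exception hierarchy for the paindraw package."""


class PainDrawError(Exception):
    """Base class for all paindraw errors."""


class InputError(PainDrawError):
    """An input file or raster is unreadable, malformed, or mismatched."""


class DegenerateReferenceError(PainDrawError):
    """The reference image yields an empty body mask (no body pixels)."""


class EmptyCohortError(PainDrawError):
    """A cohort operation was called with zero images."""


class ParameterError(PainDrawError):
    """A synthetic-fixture specification cannot be realized."""


class ReportFormatError(PainDrawError):
    """A results report file does not follow the expected dialect."""
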