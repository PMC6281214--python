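"""Exception hierarchy for the screening pipeline."""


class NiptError(Exception):
    """Base class for all niptcall errors."""


class FormatError(NiptError):
    """An input file does not match the expected layout."""


class ParameterError(NiptError, ValueError):
    """A parameter is outside its valid range."""


class DegenerateSampleError(NiptError):
    """A sample has no usable signal (e.g. zero total depth)."""


class InsufficientPanelError(NiptError):
    """Fewer reference samples than the panel requires."""


class DegeneratePanelError(NiptError):
    """Reference panel has zero spread on some chromosome."""


class DegenerateScaleError(NiptError):
    """A robust scale estimate collapsed to zero."""


class InsufficientWindowsError(NiptError):
    """A chromosome has too few merged windows for a Z statistic."""
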