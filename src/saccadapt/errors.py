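"""Package-specific exceptions and warnings."""


class SaccadaptError(Exception):
    """Base class for all errors raised by saccadapt."""


class DesignError(SaccadaptError, ValueError):
    """Invalid experiment/condition/side specification."""


class EmptySequenceError(SaccadaptError, ValueError):
    """A trial or location sequence required to be non-empty was empty."""


class NoBaselineTrialsError(SaccadaptError, ValueError):
    """No usable (non-excluded) baseline trials are available."""


class InsufficientTrialsError(SaccadaptError, ValueError):
    """Too few usable trials for the requested computation."""


class ShortSegmentError(SaccadaptError, ValueError):
    """A trace segment is too short for velocity estimation."""


class FlatSegmentError(SaccadaptError, ValueError):
    """A trace segment carries no motion, so no speed peak exists."""


class FitError(SaccadaptError, RuntimeError):
    """Model fitting failed on every restart."""


class DegenerateFitWarning(UserWarning):
    """The data carry no learning signal; w and r are unidentifiable."""


class AllMissingTraceWarning(UserWarning):
    """A gaze trace consisted entirely of missing samples."""
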