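"""Exception hierarchy for otofmr."""


class OtofmrError(Exception):
    """Base class for all otofmr errors."""


class ConfigurationError(OtofmrError):
    """A required calibration constant or coefficient is missing or invalid."""


class DataError(OtofmrError):
    """The input table cannot support the requested operation."""


class ComputationError(OtofmrError):
    """A proxy computation is undefined for the supplied values."""


class FitError(OtofmrError):
    """A model fit failed (rank deficiency, non-convergence, too few data)."""
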