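"""Exception hierarchy for aseqc.

All user-facing failures derive from :class:`AseqcError` so callers (and the
CLI) can distinguish tool errors from programming errors.
"""


class AseqcError(Exception):
    """Base class for all aseqc errors."""


class FormatError(AseqcError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class ValidationError(AseqcError, ValueError):
    """Data violates an invariant (negative counts, inconsistent totals, ...)."""


class InsufficientDataError(AseqcError):
    """A sample has too few usable genes for a reliable dispersion fit."""


class CohortTooSmallError(AseqcError):
    """Fewer than three converged fits; no cohort threshold can be derived."""
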