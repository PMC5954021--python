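"""Exception hierarchy shared across the pipeline stages."""


class GlycoEMTError(ValueError):
    """Base class for all validation and domain errors raised here."""


class InvalidInputError(GlycoEMTError):
    """An argument violates its documented precondition."""


class ZeroReferenceError(GlycoEMTError):
    """A sample's mean reference-peptide intensity is zero."""


class MissingReferenceError(GlycoEMTError):
    """A sample lacks an intensity for a required reference peptide."""


class UnusableSignatureError(GlycoEMTError):
    """A signature arm has no genes present in the expression matrix."""


class UndefinedCorrelationError(GlycoEMTError):
    """Pearson correlation requested for a constant vector."""


class InsufficientDataError(GlycoEMTError):
    """Fewer paired observations than the minimum the method needs."""
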