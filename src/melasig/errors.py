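"""Exception hierarchy for melasig."""


class MelasigError(Exception):
    """Base class for all package errors."""


class FormatError(MelasigError):
    """A file does not conform to its declared format."""


class DataIntegrityError(MelasigError):
    """Input data contradicts itself (e.g. reference-allele mismatch)."""


class EmptyResultError(MelasigError):
    """An operation removed every record/sample."""


class ParameterError(MelasigError):
    """An argument is outside its valid domain."""


class DegenerateInputError(MelasigError):
    """Input lacks the variation the operation requires."""


class AmbiguityError(MelasigError):
    """A data-driven decision is an exact tie."""


class AlignmentError(MelasigError):
    """Two tables that must share sample ids do not."""


class NumericalError(MelasigError):
    """An iterative fit failed to converge."""
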