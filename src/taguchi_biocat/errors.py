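"""Exception hierarchy for design, analysis and measurement errors."""


class TaguchiBiocatError(ValueError):
    """Base class for all package-specific errors."""


class InvalidDesignError(TaguchiBiocatError):
    """Malformed design matrix: wrong level alphabet, ragged rows, arity mismatch."""


class IncompleteDesignError(TaguchiBiocatError):
    """Response records do not cover every run of the design."""


class InvalidResponseError(TaguchiBiocatError):
    """Response values incompatible with the S/N transform (y <= 0)."""


class InvalidSelectionError(TaguchiBiocatError):
    """Unknown factor or level referenced in a selection."""


class NoResidualError(TaguchiBiocatError):
    """Saturated design analysed without pooling: zero residual degrees of freedom."""


class InvalidParameterError(TaguchiBiocatError):
    """Parameter outside its admissible range (e.g. alpha outside (0, 1))."""


class InvalidMeasurementError(TaguchiBiocatError):
    """Measurement record violating its invariants (mass, volume, extinction...)."""


class NoDecayError(TaguchiBiocatError):
    """Activity series shows no decay: deactivation rate is not positive."""
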