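"""Exception hierarchy."""


class SpliceDelayError(Exception):
    """Base class for all package errors."""


class AlignmentError(SpliceDelayError):
    """mRNA and protein time grids share no usable time range."""


class FitError(SpliceDelayError):
    """Model fitting failed (e.g. all-NaN cross-validation surface)."""


class ParseError(SpliceDelayError):
    """A tabular input file violates the expected schema."""
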