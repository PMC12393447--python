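"""Exception hierarchy shared across the package."""


class SeqGPError(Exception):
    """Base class for all package errors."""


class FormatError(SeqGPError):
    """Malformed input file (ragged sequences, missing columns, bad header)."""


class ValidationError(SeqGPError):
    """Well-formed input that violates a contract (bad symbol, negative variance)."""


class NumericalError(SeqGPError):
    """Linear-algebra failure (non-PSD kernel, factorization breakdown)."""
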