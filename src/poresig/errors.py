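"""Exception hierarchy shared across the toolkit."""


class PoresigError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PoresigError):
    """A file does not conform to its declared format."""


class InvalidSequenceError(PoresigError):
    """A nucleotide sequence contains characters outside {A,C,G,T,U}."""


class DegenerateSignalError(PoresigError):
    """Signal has zero variance and cannot be normalized."""


class AlignmentError(PoresigError):
    """A read could not be aligned (band disconnect, missing metadata...)."""


class IntegrityError(PoresigError):
    """Encoded alignment tags fail a conservation check."""


class NotFoundError(PoresigError):
    """A requested record is absent."""
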