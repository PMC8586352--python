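"""Exception hierarchy shared across psgkit modules."""


class PsgkitError(Exception):
    """Base class for all psgkit errors."""


class FormatError(PsgkitError):
    """Malformed input file or table (missing columns, duplicates, bad values)."""


class DataError(PsgkitError):
    """Input is well-formed but violates an operation's preconditions."""


class DegenerateInputError(DataError):
    """Input has no usable variation (e.g. zero-variance LFC vector)."""
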