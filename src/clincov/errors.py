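"""Exception hierarchy shared across the package."""


class ClincovError(Exception):
    """Base class for all clincov errors."""


class ParseError(ClincovError):
    """A malformed row in an input file; the message names the line."""


class FormatError(ClincovError):
    """A structurally invalid input (missing columns, empty file, ...)."""


class ContractViolationError(ClincovError):
    """A caller broke a documented precondition (e.g. unsorted coverage)."""


class UnknownGeneError(ClincovError):
    """A requested gene symbol is absent from the exon reference."""
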