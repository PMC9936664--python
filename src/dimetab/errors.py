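"""Exception types raised by the pipeline."""


class DimetabError(Exception):
    """Base class for all package errors."""


class FormatError(DimetabError):
    """An input file does not have the required columns/structure."""


class ParseError(DimetabError):
    """A cell in an input file could not be parsed as the required type."""


class ValidationError(DimetabError):
    """Inputs are structurally fine but violate a pipeline precondition."""
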