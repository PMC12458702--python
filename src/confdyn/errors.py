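"""Exception hierarchy shared across the pipeline stages."""


class ConfdynError(Exception):
    """Base class for all package errors."""


class ParseError(ConfdynError):
    """A structure or table file could not be parsed."""


class EmptyInputError(ConfdynError):
    """An input contained no usable records."""


class DegenerateGeometryError(ConfdynError):
    """A geometric operation received a degenerate configuration."""


class ParameterError(ConfdynError):
    """An out-of-range or inconsistent parameter value."""


class SelectionError(ConfdynError):
    """A residue/atom selection is empty or refers to missing entities."""
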