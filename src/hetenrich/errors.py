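"""Exception hierarchy shared across the package."""


class HetenrichError(Exception):
    """Base class for all package errors."""


class ValidationError(HetenrichError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(HetenrichError, ValueError):
    """A file could not be parsed in its declared dialect."""


class InfeasibleSimError(HetenrichError, ValueError):
    """A simulation spec requests mutually impossible parameters."""
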