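"""Exception hierarchy shared across the package."""


class PathweaverError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PathweaverError, ValueError):
    """An object violates one of its documented invariants."""


class ParseError(PathweaverError, ValueError):
    """An input file does not conform to its declared dialect."""
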