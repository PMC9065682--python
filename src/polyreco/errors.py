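"""Exception hierarchy.

All errors raised by this package derive from :class:`PolyRecoError` so
callers can catch them uniformly; the concrete classes distinguish bad
input files from bad parameters and internal contract violations.
"""


class PolyRecoError(Exception):
    """Base class for all polyreco errors."""


class FormatError(PolyRecoError, ValueError):
    """An input file does not conform to its expected layout."""


class ParameterError(PolyRecoError, ValueError):
    """A parameter value is outside its valid range."""


class LogicError(PolyRecoError, RuntimeError):
    """An internal contract was violated (e.g. boxes from different units)."""
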