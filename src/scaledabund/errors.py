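"""Exception hierarchy.

Validation problems (bad values, violated invariants, unknown identifiers)
raise :class:`ValidationError`; malformed files raise :class:`ParseError`;
configuration problems (missing internal standard, nonpositive abundances)
raise :class:`ConfigError`.  All inherit from :class:`ScaledAbundError` so
callers can catch the package's errors with one clause.
"""


class ScaledAbundError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ScaledAbundError, ValueError):
    """A table or argument violates an invariant."""


class ParseError(ScaledAbundError, ValueError):
    """A file could not be parsed as the expected format."""


class ConfigError(ScaledAbundError, ValueError):
    """An analysis configuration is missing or inconsistent."""
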