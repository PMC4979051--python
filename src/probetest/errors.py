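"""Exception hierarchy for probetest.

All errors derive from :class:`ProbetestError` so callers can catch the
package's failures with a single handler; the CLI maps them to exit codes.
"""


class ProbetestError(Exception):
    """Base class for all probetest errors."""


class ValidationError(ProbetestError, ValueError):
    """A data structure violates one of its invariants."""


class ParseError(ProbetestError, ValueError):
    """A text input file could not be parsed; message carries the location."""


class ConfigurationError(ProbetestError, ValueError):
    """A design/parameter combination is not usable."""


class DomainError(ProbetestError, ValueError):
    """An argument lies outside an operation's mathematical domain."""
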