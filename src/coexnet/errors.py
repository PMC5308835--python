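"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage=1, validation=2, I/O=3),
so library code should raise the most specific class that applies.
"""


class CoexnetError(Exception):
    """Base class for all package errors."""


class FormatError(CoexnetError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(CoexnetError):
    """Structurally well-formed input violates a semantic invariant."""


class SeedLookupError(CoexnetError):
    """The requested seed gene matches no feature or symbol."""


class UsageError(CoexnetError):
    """Invalid command-line usage or configuration keys."""
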