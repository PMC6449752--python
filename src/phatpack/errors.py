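"""Exception hierarchy for phatpack.

All errors raised on bad user input derive from :class:`PhatpackError`, so
callers (and the CLI) can catch one base class.
"""


class PhatpackError(Exception):
    """Base class for all phatpack errors."""


class FormatError(PhatpackError):
    """A file or string does not conform to its declared format."""


class AlignmentError(FormatError):
    """Sequences that must form an alignment have unequal lengths."""


class ValidationError(PhatpackError):
    """Structurally well-formed input violates a semantic invariant."""


class ConsistencyError(PhatpackError):
    """Multiple inputs that must agree (e.g. chunk reference trees) do not."""
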