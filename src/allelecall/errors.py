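"""Exception hierarchy shared by all pipeline stages."""


class AlleleCallError(Exception):
    """Base class for all package errors."""


class AlignmentError(AlleleCallError):
    """Sequences are not a valid alignment (e.g. unequal lengths)."""


class FormatError(AlleleCallError):
    """A file or record violates the expected format."""


class RegionError(AlleleCallError):
    """A region map is invalid or a requested region does not exist."""


class PaintingError(AlleleCallError):
    """Ancestry painting is impossible (e.g. no informative sites)."""


class PreconditionError(AlleleCallError):
    """An operation was called with unmet preconditions."""
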