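"""Exception hierarchy shared by all markerkit modules."""


class MarkerKitError(Exception):
    """Base class for all markerkit errors."""


class ParseError(MarkerKitError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(MarkerKitError):
    """An in-memory object violates a structural invariant."""


class MergeError(MarkerKitError):
    """Band matrices could not be merged (taxon sets differ)."""


class SaturationError(MarkerKitError):
    """A substitution-model distance is undefined (log argument <= 0)."""


class DesignError(MarkerKitError):
    """Primer design is impossible on the given fragment/constraints."""
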