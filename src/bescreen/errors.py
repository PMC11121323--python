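"""Exception hierarchy shared across the package."""


class BescreenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BescreenError, ValueError):
    """Malformed textual input (coordinates, sequences, IUPAC patterns)."""


class DomainError(BescreenError, ValueError):
    """Arguments outside the operation's domain (bad bases, bad ranges)."""


class OutOfModelError(BescreenError, ValueError):
    """A coordinate or window falls outside the modeled transcript slice."""


class UnknownConstructError(BescreenError, KeyError):
    """Editor construct name not present in the registry."""


class ValidationError(BescreenError, ValueError):
    """Structurally invalid model objects (segments, registries, reports)."""
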