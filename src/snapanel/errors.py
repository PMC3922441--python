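"""Exception hierarchy for snapanel."""


class SnapanelError(Exception):
    """Base class for all snapanel errors."""


class AlphabetError(SnapanelError):
    """A sequence contains characters outside the allowed nucleotide alphabet."""


class ValidationError(SnapanelError):
    """A domain object or argument violates one of its invariants."""


class CoverageError(SnapanelError):
    """A reference window does not cover a required footprint or amplicon."""


class AmbiguityError(SnapanelError):
    """A primer footprint contains ambiguous (N) bases."""


class CapacityError(SnapanelError):
    """A spacing problem cannot fit inside the readable sizing window."""


class ConstructionError(SnapanelError):
    """Toy-genome or panel construction is impossible from the given inputs."""


class ParseError(SnapanelError):
    """A file could not be parsed; the message names the offending row."""


class FixtureError(SnapanelError):
    """Packaged fixture data failed its integrity check."""
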