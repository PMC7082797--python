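"""Exception hierarchy for rflpkit.

All data-level failures derive from :class:`RflpkitError` so callers (and the
CLI) can distinguish bad input from programming errors.
"""


class RflpkitError(Exception):
    """Base class for all rflpkit data errors."""


class EmptyInput(RflpkitError):
    """An input stream or file contained no records."""


class AlphabetError(RflpkitError):
    """A sequence contains a symbol outside the 15-letter IUPAC DNA alphabet.

    Carries the offending record id and 0-based position where available.
    """

    def __init__(self, message: str, record: str | None = None,
                 position: int | None = None):
        super().__init__(message)
        self.record = record
        self.position = position


class NoMatchPossible(RflpkitError):
    """A primer is longer than the template it is matched against."""


class EmptyPattern(RflpkitError):
    """Every fragment of a digest fell below the gel's visibility cutoff."""


class IncomparablePatterns(RflpkitError):
    """Band patterns from different enzymes or gene regions were compared."""


class IndistinguishableSpecies(RflpkitError):
    """Two species share an identical band pattern under the gel model."""

    def __init__(self, species_a: str, species_b: str, bands):
        self.species_a = species_a
        self.species_b = species_b
        self.bands = list(bands)
        super().__init__(
            f"species {species_a!r} and {species_b!r} share the band "
            f"pattern {self.bands} and cannot be separated"
        )


class KeyConstructionFailure(RflpkitError):
    """No candidate feature can split a set of patterns any further."""


class KeyParseError(RflpkitError):
    """A key file line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class EmptyLibrary(RflpkitError):
    """An enzyme screen was requested with no enzymes to screen."""


class InfeasibleConfig(RflpkitError):
    """A synthetic-dataset configuration cannot be realised geometrically."""
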