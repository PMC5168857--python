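"""Exception hierarchy for ino-mine."""


class InoMineError(Exception):
    """Base class for all ino-mine errors."""


class MalformedPatternError(InoMineError):
    """A keyword or dependency pattern annotation could not be parsed."""


class OntologyError(InoMineError):
    """Structural problem in the interaction-type dictionary (cycle, missing column...)."""


class TermNotFoundError(OntologyError, KeyError):
    """An IRI was looked up that the ontology does not contain."""


class EmptySentenceError(InoMineError):
    """Tokenization was asked for an empty or whitespace-only sentence."""


class InvalidPairError(InoMineError):
    """Two mentions passed as a pair overlap or belong to different sentences."""


class ConlluParseError(InoMineError):
    """A CoNLL-U stream violated the 10-column format."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EnrichmentError(InoMineError):
    """A 2x2 enrichment table had a zero margin or inconsistent totals."""
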