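"""Exception hierarchy for readrsa."""


class ReadRsaError(Exception):
    """Base class for all readrsa errors."""


class EncodingError(ReadRsaError):
    """A symbol cannot be encoded under the given slot scheme."""


class LexiconFormatError(ReadRsaError):
    """A lexicon / scheme / rules file is malformed or violates invariants."""


class UnpronounceableInputError(ReadRsaError):
    """No grapheme-phoneme rule matches at some position of a spelling."""

    def __init__(self, spelling: str, position: int):
        self.spelling = spelling
        self.position = position
        super().__init__(
            f"no rule matches {spelling!r} at position {position}"
        )


class DegenerateDataError(ReadRsaError):
    """Zero-variance or otherwise degenerate input to a statistical routine."""


class ConfigError(ReadRsaError):
    """Invalid pipeline configuration."""
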