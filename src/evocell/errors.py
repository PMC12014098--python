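"""Typed error hierarchy.

Every user-facing failure raises a subclass of :class:`EvoCellError` so the
CLI can map errors to exit codes and print the class name.
"""


class EvoCellError(Exception):
    """Base class for all evocell errors."""


class SchemaError(EvoCellError):
    """An input file is missing a required column or section."""


class IntegrityError(EvoCellError):
    """Cross-file referential integrity violated (e.g. unknown cell ids)."""


class DataValueError(EvoCellError):
    """A value is out of domain (negative count, non-integer count, ...)."""


class ParameterError(EvoCellError):
    """A caller-supplied parameter is out of range or unknown."""


class EmptyRegionError(EvoCellError):
    """A selected cell region is empty and cannot feed downstream analysis."""


class GmtParseError(EvoCellError):
    """A GMT gene-set file line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class PromptError(EvoCellError):
    """Prompt template missing or a required context field absent."""


class ProviderParseError(EvoCellError):
    """LLM provider output did not follow the expected layout.

    Retains the raw provider text for auditing.
    """

    def __init__(self, message: str, raw_text: str = ""):
        super().__init__(message)
        self.raw_text = raw_text


class ProviderTransportError(EvoCellError):
    """LLM provider transport failure (timeout, HTTP error, ...)."""


class PubMedTransportError(EvoCellError):
    """PubMed client transport failure, distinct from 'no match'."""
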