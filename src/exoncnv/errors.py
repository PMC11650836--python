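"""Exception hierarchy shared by all exoncnv modules.

User-facing errors (bad files, bad configuration, empty content) derive from
:class:`ExonCnvError`; the CLI maps them to exit code 1 and anything else to
exit code 2.
"""


class ExonCnvError(Exception):
    """Base class for all errors raised deliberately by this package."""


class SchemaError(ExonCnvError):
    """A table is missing required columns (the message names them)."""


class ParseError(ExonCnvError):
    """A cell could not be parsed; the message carries the 1-based data row."""


class ConfigError(ExonCnvError):
    """Invalid user configuration: filters, region strings, env keys, specs."""


class ContentError(ExonCnvError):
    """An input was structurally valid but empty where content is required."""


class VcfFormatError(ExonCnvError):
    """A VCF file could not be opened or decoded."""


class GeneNotFoundError(ExonCnvError, LookupError):
    """A gene is absent from a reference; carries prefix-matched suggestions."""

    def __init__(self, gene: str, suggestions: list[str] | None = None):
        self.gene = gene
        self.suggestions = suggestions or []
        hint = f" (did you mean: {', '.join(self.suggestions)}?)" if self.suggestions else ""
        super().__init__(f"gene {gene!r} not found in reference{hint}")


class ChromosomeNotFoundError(ExonCnvError, LookupError):
    """A requested chromosome has no data."""
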