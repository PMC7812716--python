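"""Exception hierarchy shared across the package.

Errors are categorized so the CLI can map them to exit codes:
usage errors (bad arguments), input-format errors (unparseable files),
transport errors (remote endpoint failures) and export errors.
"""


class PaxnetError(Exception):
    """Base class for all package errors."""


class UsageError(PaxnetError):
    """Caller violated a precondition (empty input, bad flag combination)."""


class InputFormatError(PaxnetError):
    """An input file failed to parse (RDF, gene list, synonym table)."""


class TransportError(PaxnetError):
    """A remote SPARQL endpoint could not be reached or kept failing."""

    def __init__(self, message: str, endpoint: str = "", attempts: int = 0):
        super().__init__(message)
        self.endpoint = endpoint
        self.attempts = attempts


class MalformedResultsError(PaxnetError):
    """Query results lack a variable the downstream parser requires."""


class ExportError(PaxnetError):
    """An output file could not be written in the requested form."""
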