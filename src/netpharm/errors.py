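"""Exception hierarchy shared across the package.

All input/format problems derive from :class:`NetpharmError` so the CLI can
map them to stable exit codes (2 for input errors, 3 for stage failures).
"""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetpharmError):
    """A file does not conform to the expected schema (e.g. missing column)."""


class ParseError(NetpharmError):
    """A row or line could not be parsed; message carries the line number."""


class DomainError(NetpharmError):
    """An argument is outside its mathematical domain."""


class ConvergenceError(NetpharmError):
    """An iterative numerical routine failed to converge within its cap."""


class CliqueCapExceeded(NetpharmError):
    """Maximal-clique enumeration exceeded the configured safety cap."""


class StageError(NetpharmError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
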