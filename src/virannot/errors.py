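"""Exception hierarchy.

Exit-code mapping in the CLI: usage errors -> 1, data integrity -> 2.
"""


class VirannotError(Exception):
    """Base class for all virannot errors."""


class ParseError(VirannotError):
    """A malformed record in an input file; carries the 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class IntegrityError(VirannotError):
    """Internally inconsistent data (orphan taxids, duplicated reads, ...)."""
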