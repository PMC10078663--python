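"""Exception hierarchy.

``PhytomarkError`` is the base; the CLI maps ``UsageError`` (click) to exit
code 2 and any ``PhytomarkError`` to exit code 3.
"""


class PhytomarkError(Exception):
    """Base class for all phytomark errors."""


class ParseError(PhytomarkError):
    """Malformed input file (carries file context and line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PhytomarkError):
    """A domain invariant was violated (duplicate ids, bad labels, bad bounds)."""
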