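"""Exception hierarchy shared across the pipeline stages.

Error classes are deliberately fine-grained so the labeling stage can tell
apart "the vessel is not there" (snap failure -> undetected) from "the two
endpoints sit in different skeleton components" (no path -> failed).
"""


class CowLabelError(Exception):
    """Base class for all package errors."""


class InputError(CowLabelError):
    """Invalid argument or malformed input data; names the offending field."""


class DegenerateInputError(InputError):
    """Input is structurally valid but degenerate (e.g. constant volume)."""


class UndefinedAccuracyError(InputError):
    """Accuracy requested for a segment with no found paths at all."""


class ParseError(InputError):
    """Endpoint-annotation text could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SnapError(CowLabelError):
    """No skeleton voxel within the allowed radius of an annotated point."""


class NoPathError(CowLabelError):
    """The goal node is unreachable from the start node."""


class OracleRefusedError(CowLabelError):
    """The brute-force path oracle declined an input too large to enumerate."""
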