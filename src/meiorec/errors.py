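"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ``FormatError`` -> 2, ``StageError`` -> 3,
anything else propagates as an ordinary traceback (exit 1).
"""


class MeiorecError(Exception):
    """Base class for all package errors."""


class ParameterError(MeiorecError, ValueError):
    """Invalid parameter value (negative rate, zero depth, ...)."""


class FormatError(MeiorecError, ValueError):
    """Malformed input file or table (wrong strand count, unsorted positions, ...)."""


class StageError(MeiorecError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
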