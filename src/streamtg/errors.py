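"""Exception types shared across the package."""


class StreamTgError(Exception):
    """Base class for all package-specific errors."""


class GraphFormatError(StreamTgError, ValueError):
    """Malformed dynamic-graph content (file dialect or in-memory invariants).

    Carries an optional 1-based line number when raised by a parser.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TrajectoryFormatError(StreamTgError, ValueError):
    """Malformed trajectory file or inconsistent frames."""


class ParameterError(StreamTgError, ValueError):
    """Infeasible or out-of-range user parameters."""


class InputError(StreamTgError, ValueError):
    """Invalid in-memory input to a computation (bad matrix, bad id, ...)."""


class StateCorruptionError(StreamTgError, RuntimeError):
    """An edge update contradicts the tracked adjacency state.

    Adding an edge whose bit is already set (or removing an unset one) means
    the update stream is inconsistent with the maintained ids.
    """
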