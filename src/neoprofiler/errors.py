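"""Exception hierarchy shared across the pipeline.

Each stage raises a specific subclass so the CLI can map failures onto
distinct exit codes (parse vs. validation vs. stage execution).
"""


class NeoprofilerError(Exception):
    """Base class for all package errors."""


class ParameterError(NeoprofilerError, ValueError):
    """A configuration or function parameter violates its contract."""


class InputError(NeoprofilerError, ValueError):
    """An input value or record violates its invariants."""


class ParseError(NeoprofilerError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)


class CoordinateError(InputError):
    """A position falls outside the coordinate system it refers to."""


class ConsistencyError(InputError):
    """Two inputs that must agree (e.g. ref base vs. transcript) do not."""


class CoverageError(NeoprofilerError, KeyError):
    """A required (peptide, allele) affinity is missing in strict mode."""


class StateError(NeoprofilerError, RuntimeError):
    """An object was used before a required processing step."""


class StageError(NeoprofilerError, RuntimeError):
    """A pipeline stage failed; names the stage and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
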