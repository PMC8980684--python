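"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented contract."""


class RangeError(ValidationError):
    """A location or extent falls outside its admissible range."""


class StructureError(ValidationError):
    """A vessel-tree topology is malformed (cycle, duplicate id, disconnect)."""


class SchemaError(ValidationError):
    """A serialized file violates the expected schema.

    ``path`` is a JSON-pointer-style location of the offending field.
    """

    def __init__(self, message: str, path: str = "/"):
        super().__init__(f"{path}: {message}")
        self.path = path


class SolverError(RuntimeError):
    """The steady-flow solver failed; carries the last residual."""

    def __init__(self, message: str, residual: float = float("nan"), iterations: int = 0):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class CalibrationError(RuntimeError):
    """Boundary-parameter optimization failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NotOnTreeError(LookupError):
    """A lesion or probe location refers to a segment absent from the tree."""


class InfeasibleCohortError(RuntimeError):
    """The cohort configuration cannot be realized (target strata unreachable)."""


class TrialStageError(RuntimeError):
    """An end-to-end trial stage failed; names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
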