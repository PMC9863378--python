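"""Exception hierarchy for the qsarpt pipeline."""


class QsarError(Exception):
    """Base class for all qsarpt errors."""


class SchemaCollisionError(QsarError):
    """Two descriptor codes collide after concatenation."""


class FormatError(QsarError):
    """A file does not conform to the expected dialect."""


class ParseError(FormatError):
    """A cell could not be parsed; carries row/column context."""


class MissingValueError(QsarError):
    """An operation that requires a complete matrix met missing values."""


class TruncatedPeakError(QsarError):
    """The signal does not cross the threshold level inside the trace."""


class MultiPeakError(QsarError):
    """More than one disjoint region above half height."""


class ReferenceMissingError(QsarError):
    """No reference-compound trace for a chromatographic condition."""


class DuplicateTraceError(QsarError):
    """A compound was measured twice on the same condition."""


class DomainError(QsarError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class ConvergenceError(QsarError):
    """Training failed to converge; ``result`` holds the best partial state."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


class CollinearityError(QsarError):
    """Rank-deficient regression design; names the dependent columns."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class InsufficientDataError(QsarError):
    """Fewer observations than parameters to estimate."""


class UnknownDescriptorError(QsarError, KeyError):
    """A requested descriptor code is not present in the matrix/schema."""


class SplitConflictError(QsarError):
    """A pinned compound was requested in a test set."""


class PipelineStageError(QsarError):
    """A pipeline stage failed; carries the stage name and partial state."""

    def __init__(self, stage, message, state_path=None):
        super().__init__(f"stage={stage}: {message}")
        self.stage = stage
        self.state_path = state_path
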