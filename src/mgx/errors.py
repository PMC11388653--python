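"""Exception hierarchy shared across the pipeline stages."""


class MgxError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MgxError):
    """Malformed input file (ragged rows, missing label row, ...)."""


class ParseError(FormatError):
    """Non-numeric cell where an intensity was expected."""


class LabelError(MgxError):
    """Unknown class-label token."""


class ConfigError(MgxError):
    """Invalid run configuration or hyperparameter."""


class InputError(MgxError):
    """Invalid numerical input to an operation."""


class SimulationError(MgxError):
    """Impossible synthetic-data specification (e.g. block overflow)."""


class DegenerateFluctuationError(MgxError):
    """All detrended residuals vanish; the scaling exponent is undefined."""


class SingularDesignError(MgxError):
    """Rank-deficient regression design matrix."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientDataError(MgxError):
    """Too few samples in a class for the requested statistic."""


class ConstraintError(MgxError):
    """Regression-target constraint violated."""


class StratificationError(MgxError):
    """A cross-validation fold lost one of the classes."""


class FitError(MgxError):
    """Classifier could not be fitted (e.g. a class absent)."""


class PredictError(MgxError):
    """Prediction input incompatible with the fitted model."""


class AmbiguityError(MgxError):
    """Confusion-matrix reconstruction found zero or multiple candidates."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = tuple(candidates)
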