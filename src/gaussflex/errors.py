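"""Exception hierarchy shared across the package."""


class GaussflexError(Exception):
    """Base class for all package errors."""


class ParseError(GaussflexError):
    """A structure or table file could not be parsed."""


class FormatError(GaussflexError):
    """Unknown or unsupported file format."""


class SchemaError(GaussflexError):
    """A tabular artifact does not match its expected schema."""


class DegenerateInputError(GaussflexError):
    """Input is geometrically or statistically degenerate (too short, zero length, ...)."""


class ShapeError(GaussflexError):
    """Array shapes are inconsistent."""


class ParameterError(GaussflexError):
    """An invalid parameter value was supplied."""


class DataError(GaussflexError):
    """Invalid values inside otherwise well-formed data (NaN, empty partition, ...)."""


class MetricError(GaussflexError):
    """A metric is undefined for the given inputs (single class, zero variance, ...)."""


class CapabilityError(GaussflexError):
    """The requested operation is not supported by this model type."""


class StratificationError(GaussflexError):
    """A class is too small to stratify over the requested folds."""


class JoinError(GaussflexError):
    """Id sets of two artifacts do not match."""


class GenerationError(GaussflexError):
    """A synthetic generator failed to satisfy its constraints."""


class StageError(GaussflexError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
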