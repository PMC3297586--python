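"""Exception hierarchy for the pipeline.

Every error raised on purpose derives from :class:`GiquantError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class GiquantError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(GiquantError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidInputError(GiquantError):
    """A value passed to an operation is outside its domain."""


class InvalidRecordError(GiquantError):
    """A data record violates its type invariants."""


class LayoutError(GiquantError):
    """A simulated plate layout does not fit on a 96-well plate."""


class DuplicateRecordError(GiquantError):
    """Two records share a key that must be unique."""


class FormatError(GiquantError):
    """A file's structure or a cell's contents cannot be parsed."""


class MissingWellError(GiquantError):
    """A well named in the plate map is absent from the time-series file."""


class SchemaError(GiquantError):
    """A table is missing a required column, or a config value is out of range."""


class InsufficientDataError(GiquantError):
    """Too few points for the requested numerical operation."""


class DegenerateCurveError(GiquantError):
    """A growth curve whose area is non-positive has no log fitness."""


class NormalizationError(GiquantError):
    """A plate cannot be normalized (no wild-type wells)."""


class IncompleteDesignError(GiquantError):
    """A double-mutant cell lacks one of its single-mutant cells."""


class MissingViabilityError(GiquantError):
    """An estimated pair has no random-spore viability record."""


class ConsistencyError(GiquantError):
    """A validation outcome references a pair that was never a candidate."""
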