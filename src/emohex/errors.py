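"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`EmohexError`;
anything else escaping the package is a genuine bug.
"""


class EmohexError(Exception):
    """Base class for all package errors."""


class SpecificationError(EmohexError):
    """A cohort specification violates its invariants (sizes, probabilities)."""


class ValidationError(EmohexError):
    """An input record carries an out-of-range or unknown value."""


class MissingCellError(EmohexError):
    """A participant has zero scored presentations for a required feature cell."""


class SingularDesignError(EmohexError):
    """The covariate design matrix is rank deficient."""


class DegenerateFeatureError(EmohexError):
    """A feature column has (numerically) zero residual variance."""


class DegenerateVectorError(EmohexError):
    """A vector has zero generalized norm under the relevance metric."""


class DegenerateGeometryError(EmohexError):
    """Distances to the nearest correct and incorrect prototypes both vanish."""


class DivergenceError(EmohexError):
    """Training produced a non-finite cost."""


class SchemaError(EmohexError):
    """Column names or ordering do not match what the model was trained on."""


class StratificationError(EmohexError):
    """A class is too small to appear in both the training and test partitions."""


class UndefinedMetricError(EmohexError):
    """A performance metric is undefined (empty class in the test partition)."""


class EmptyAggregateError(EmohexError):
    """No classifier runs survived the relevance retention threshold."""


class ZeroVarianceError(EmohexError):
    """All observations are identical; a rank test is undefined."""
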