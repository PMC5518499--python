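"""Named exception types raised across the package."""


class EvoHISError(Exception):
    """Base class for all package-specific errors."""


class LabelColumnError(EvoHISError):
    """The requested label column is not present in the input file."""


class ClassCountError(EvoHISError):
    """The label column does not contain exactly two distinct values."""


class UnimputableFeatureError(EvoHISError):
    """A feature is entirely missing and cannot be imputed."""


class EmptyResampleError(EvoHISError):
    """The requested resample size rounds to zero instances."""


class UndefinedObjectiveError(EvoHISError):
    """Specificity or sensitivity is undefined (a class has no instances)."""


class WeightConstraintError(EvoHISError):
    """Objective weights violate the totality or nonnegativity constraints."""


class BoundViolationError(EvoHISError):
    """A parameter vector lies outside its declared box bounds."""


class DegenerateFoldError(EvoHISError):
    """A training fold contains a single class."""


class EvaluationError(EvoHISError):
    """A fitness evaluation returned a non-finite value.

    Carries the offending position on the ``position`` attribute.
    """

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class EmptyFrontError(EvoHISError):
    """A front metric was requested on an empty point set."""


class FrontSizeError(EvoHISError):
    """Spacing requires at least two front members."""


class DegenerateTestError(EvoHISError):
    """A statistical test's preconditions are unmet (e.g. zero variance)."""
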