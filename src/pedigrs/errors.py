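"""Exception hierarchy used across the package."""


class PedigrsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PedigrsError):
    """A simulation or analysis configuration violates its invariants."""


class DataError(PedigrsError):
    """Input data are malformed or violate a precondition."""


class SnpMismatchError(DataError):
    """SNP identifiers of two inputs do not match.

    Carries the symmetric difference so callers can report which SNPs
    are missing from which side.
    """

    def __init__(self, message: str, only_left=(), only_right=()):
        super().__init__(message)
        self.only_left = tuple(only_left)
        self.only_right = tuple(only_right)


class SeparationError(PedigrsError):
    """A logistic model is (quasi-)perfectly separated and has no finite MLE."""


class UnclassifiableTrajectoryError(PedigrsError):
    """A (baseline, follow-up) status combination is outside the declared
    trajectory-group mapping."""

    def __init__(self, combination):
        self.combination = combination
        super().__init__(
            "trajectory combination not covered by the group mapping: "
            f"{combination!r}"
        )
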