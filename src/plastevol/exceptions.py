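"""Exception types shared across the package."""


class PlastevolError(Exception):
    """Base class for package-specific errors."""


class DesignError(PlastevolError):
    """Invalid experimental-design inputs (duplicate levels, unknown treatments)."""


class EmptySampleError(PlastevolError):
    """A per-sample quantity was requested for a sample with no records."""


class RankDeficiencyError(PlastevolError):
    """Fixed-effect design matrix is rank deficient.

    Carries the aliased term names so callers can report *which* effects are
    inestimable instead of silently dropping them.
    """

    def __init__(self, aliased):
        self.aliased = tuple(aliased)
        super().__init__(
            "fixed-effect design is rank deficient; aliased terms: "
            + ", ".join(self.aliased)
        )


class SingleLevelFactorError(PlastevolError):
    """A declared random factor has fewer than two levels."""


class ConvergenceError(PlastevolError):
    """Mixed-model optimisation failed to converge."""


class ConfoundedSamplesError(PlastevolError):
    """A genetic contrast was requested on samples still containing competitors."""

    def __init__(self, contaminated_samples):
        self.contaminated_samples = tuple(contaminated_samples)
        super().__init__(
            "competitor records present in compared samples (pass "
            "allow_confounded=True to acknowledge the confounding): "
            + ", ".join(map(str, self.contaminated_samples))
        )


class NotComputableError(PlastevolError):
    """The requested analysis is not computable from the available data."""
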