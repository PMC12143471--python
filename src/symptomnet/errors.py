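"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (thresholds, seeds, iteration counts...)."""


class CohortFormatError(ValueError):
    """A cohort file violates the expected CSV schema."""


class UndefinedResultError(ValueError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""
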