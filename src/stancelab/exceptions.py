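"""Exception hierarchy shared across the pipeline."""


class StancelabError(Exception):
    """Base class for all package-specific errors."""


class CohortValidationError(StancelabError, ValueError):
    """A cohort file or record violates the documented schema."""


class DegenerateTraceError(StancelabError, ValueError):
    """A moment trace is constant (zero variance or zero peak-to-peak),
    so standardized peaks / nRMSE are undefined for it."""


class ConfigError(StancelabError, ValueError):
    """Invalid configuration values (fractions, bands, probabilities...)."""
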