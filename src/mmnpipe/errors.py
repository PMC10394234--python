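"""Exception hierarchy shared across the pipeline."""


class MMNPipeError(Exception):
    """Base class for all mmnpipe errors."""


class ConfigurationError(MMNPipeError):
    """Invalid or inconsistent configuration (unknown layout, bad cutoff...)."""


class DomainError(MMNPipeError):
    """Input outside the physical/mathematical domain of an operation."""


class NumericalError(MMNPipeError):
    """A numerical procedure failed to converge or lost precision."""


class ModelError(MMNPipeError):
    """A source/forward model is structurally unusable (e.g. rank deficient)."""


class FormatError(MMNPipeError):
    """On-disk data does not conform to the expected file format."""


class StatisticsError(MMNPipeError):
    """A statistical routine received data it cannot analyze."""


class SeparationError(StatisticsError):
    """Logistic regression outcome is perfectly separated by a predictor."""


class DesignError(MMNPipeError):
    """A cohort design is internally inconsistent."""
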