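"""Exception hierarchy shared across the pipeline stages."""


class OxyscaleError(Exception):
    """Base class for all oxyscale errors."""


class FormatError(OxyscaleError):
    """An input file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(OxyscaleError):
    """Data violate an invariant of the embryo event-time data model."""


class CensoringError(OxyscaleError):
    """An operation needs an event that the embryo never reached."""


class DegenerateDataError(OxyscaleError):
    """Data are formally valid but carry no usable signal (e.g. zero anchor interval)."""


class DegenerateDesignError(OxyscaleError):
    """The predictor design cannot identify the requested fit (e.g. a single oxygen level)."""


class SampleSizeError(OxyscaleError):
    """Too few observations for the requested fit or test."""


class DomainError(OxyscaleError):
    """Predictor or response values fall outside a model family's domain."""


class SelectionError(OxyscaleError):
    """No candidate model could be fitted, so none can be selected."""


class FitError(OxyscaleError):
    """Nonlinear fitting failed on every candidate."""


class ConfigError(OxyscaleError):
    """A run or generator configuration is invalid."""
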