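"""Exception hierarchy."""


class FaersigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FaersigError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(FaersigError):
    """A file does not follow the expected FAERS ASCII dialect."""


class UndefinedStatisticError(FaersigError):
    """A disproportionality statistic is undefined for the given table."""


class EvaluationError(FaersigError):
    """Signal evaluation requested with missing statistics."""
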