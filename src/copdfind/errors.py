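"""Exception hierarchy shared across the package.

Three broad families map onto distinct CLI exit codes: configuration
problems (bad config file, unknown algorithm, invalid criterion), data
problems (schema violations, referential-integrity failures, unparseable
rows), and statistical problems (undefined estimates, degenerate tables).
"""


class CopdfindError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CopdfindError):
    """Invalid configuration: bad field value, unknown name, missing section."""


class DataError(CopdfindError):
    """Invalid input data."""


class SchemaError(DataError):
    """A table is missing a required column or has a malformed header."""


class IntegrityError(DataError):
    """Referential-integrity violation between linked tables."""


class StatisticalError(CopdfindError):
    """A requested statistic is undefined for the given input."""
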