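"""Exception hierarchy shared across the pipeline stages."""


class DenovoprioError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DenovoprioError):
    """Invalid configuration: bad thresholds, generator settings, region lists."""


class SchemaError(DenovoprioError):
    """Input file is missing a required field, column, or header definition."""


class DataError(DenovoprioError):
    """Input data violates a contract (duplicates, degenerate tables, empty strata)."""
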