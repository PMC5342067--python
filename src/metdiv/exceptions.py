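"""Exception hierarchy for metdiv."""


class MetdivError(Exception):
    """Base class for all metdiv errors."""


class SchemaError(MetdivError, ValueError):
    """A table is missing required columns."""


class ValidationError(MetdivError, ValueError):
    """A table row or value violates the data contract."""


class ConfigError(MetdivError, ValueError):
    """A cohort or pipeline configuration is invalid."""


class DegenerateDataError(MetdivError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant scores)."""
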