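"""Exception hierarchy for cohort validation and analysis configuration."""


class NpcPermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NpcPermError):
    """A user-supplied configuration (column names, scheme, specs) is invalid."""


class DataError(NpcPermError):
    """The cohort data violate a structural requirement (group levels, categories)."""


class DegenerateVariableError(DataError):
    """A variable has no usable observations in one group, or no variation at all."""
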