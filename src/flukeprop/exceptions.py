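"""Exception hierarchy for flukeprop."""


class FlukepropError(Exception):
    """Base class for all flukeprop errors."""


class InvalidInputError(FlukepropError, ValueError):
    """A function argument violates its physical or numeric preconditions."""


class ConfigurationError(FlukepropError):
    """A required configuration item is missing or inconsistent."""


class SchemaError(FlukepropError):
    """An input table is missing required columns."""


class DataError(FlukepropError):
    """An input table has malformed rows (non-monotone time, duplicates, ...)."""


class SimulationError(FlukepropError):
    """The synthetic-deployment integrator became unphysical."""


class EstimationError(FlukepropError):
    """An estimate cannot be formed from the available beats."""
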