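"""Exception hierarchy shared across the pipeline."""


class PPActivError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PPActivError, ValueError):
    """A file does not follow the expected on-disk dialect."""


class SchemaError(PPActivError, ValueError):
    """A table is missing required columns."""


class ValidationError(PPActivError, ValueError):
    """Parsed values violate a domain invariant."""


class ConfigurationError(PPActivError, ValueError):
    """A requested computation cannot be set up from the given inputs."""


class RangeError(PPActivError, ValueError):
    """A requested time span falls outside the available data."""


class DegenerateDesignError(PPActivError, ValueError):
    """A regression design matrix is rank deficient or constant."""


class NumericalError(PPActivError, RuntimeError):
    """A linear-algebra step failed beyond the configured regularisation."""


class EmptySeriesError(PPActivError, ValueError):
    """An operation received a series with no usable observations."""


class SpecificationError(PPActivError, ValueError):
    """A synthetic-cohort specification is internally inconsistent."""
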