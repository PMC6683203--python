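"""Exception hierarchy shared across the package."""


class SublethalError(Exception):
    """Base class for package errors."""


class ConfigurationError(SublethalError):
    """A parameter set, design or run configuration is incomplete or invalid."""


class SchemaError(SublethalError):
    """Cohort data do not match the expected column schema."""


class ShortfallError(SublethalError):
    """Not enough surviving adults to realise the mating design."""

    def __init__(self, message: str, needed: int | None = None,
                 available: int | None = None):
        super().__init__(message)
        self.needed = needed
        self.available = available


class SamplerError(SublethalError):
    """The MCMC sampler could not be initialised or failed mid-run."""


class ReductionError(SublethalError):
    """Model reduction was asked about a term with no posterior summary."""
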