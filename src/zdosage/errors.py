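"""Exception types shared across the package."""


class ZdosageError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(ZdosageError):
    """A simulation or pipeline configuration field is out of range or missing."""


class InputError(ZdosageError):
    """An input table violates a precondition (missing column, bad value, empty group)."""


class DegenerateDesignError(ZdosageError):
    """A regression design is singular or underdetermined (e.g. constant covariate)."""
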