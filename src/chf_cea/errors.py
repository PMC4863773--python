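"""Exception hierarchy for the model package."""


class ModelError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ModelError):
    """A configuration file is missing a field or holds an invalid value."""


class NormalizationError(ConfigError):
    """A transition row does not sum to 1 beyond the correctable band."""

    def __init__(self, row_label: str, row_sum: float, tol: float):
        self.row_label = row_label
        self.row_sum = row_sum
        super().__init__(
            f"transition row {row_label!r} sums to {row_sum:.10g} "
            f"(must be 1 within {tol:g})"
        )


class ValidationError(ModelError):
    """A domain object violates one of its invariants."""


class InfeasibleProbabilityError(ModelError):
    """A transformed probability left the [0, 1] interval."""

    def __init__(self, entry: str, value: float):
        self.entry = entry
        self.value = value
        super().__init__(f"entry {entry!r} became {value:.10g}, outside [0, 1]")


class UnknownScenarioError(ModelError):
    """Requested scenario name is not registered."""
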