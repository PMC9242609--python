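"""Exception hierarchy shared across the package."""


class ChwIncentivesError(Exception):
    """Base class for all package errors."""


class SchemaError(ChwIncentivesError):
    """An input file does not parse as the documented schema."""


class CatalogValidationError(ChwIncentivesError):
    """One or more incentive definitions violate their invariants.

    Carries the full list of violations so callers see everything at once.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "catalog validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class ConfigurationError(ChwIncentivesError):
    """A referenced key (rate, demographic basis, path) cannot be resolved."""


class ContractError(ChwIncentivesError):
    """An operation was called outside its documented precondition."""
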