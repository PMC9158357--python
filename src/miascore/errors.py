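"""Exception hierarchy shared across the package."""


class MiaError(Exception):
    """Base class for all package errors."""


class CohortParseError(MiaError, ValueError):
    """A CSV cell could not be interpreted (unknown label, bad number).

    Carries enough context to name the offending row.
    """


class CohortValidationError(MiaError, ValueError):
    """A structural invariant of a patient or cohort is violated."""


class ConfigurationError(MiaError, ValueError):
    """An invalid generator or run configuration."""


class ContractError(MiaError, ValueError):
    """An operation was called outside its stated preconditions."""
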