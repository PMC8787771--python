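"""Exception hierarchy for bayeshte."""


class BayesHTEError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BayesHTEError):
    """A configuration value is invalid; the message names the offending field."""


class InputError(BayesHTEError):
    """Input data violate a precondition of an operation."""


class ContractError(BayesHTEError):
    """An internal contract between pipeline stages was violated."""


class MissingnessGateError(InputError):
    """Per-analysis missingness is at or above the complete-case threshold."""
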