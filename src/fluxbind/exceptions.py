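"""Exception hierarchy for fluxbind."""


class FluxbindError(Exception):
    """Base class for all fluxbind errors."""


class InvalidInputError(FluxbindError, ValueError):
    """An argument violates a documented precondition."""


class SingularityError(FluxbindError, ValueError):
    """An evaluation was requested at a singular configuration (e.g. zero distance)."""


class IntegrationError(FluxbindError, RuntimeError):
    """Dynamics produced a non-finite state; the offending state is named in the message."""


class ConfigurationError(FluxbindError, ValueError):
    """A run configuration failed validation; the message lists every failing field."""


class UndefinedRatioError(FluxbindError, ZeroDivisionError):
    """Both fluxes are zero, so the ensemble-probability ratio is undefined."""
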