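"""Exception hierarchy for cgtension."""


class CGTensionError(Exception):
    """Base class for all package errors."""


class ParameterError(CGTensionError, ValueError):
    """A physical or model parameter is out of its valid domain."""


class PlacementError(CGTensionError, RuntimeError):
    """Synthetic objects (cells, spots) could not be placed without overlap."""


class FitQualityError(CGTensionError, RuntimeError):
    """A fit failed to converge or its solution sits on a boundary.

    Carries a ``diagnostics`` dict (fit range, parameter values, residual)
    so callers can report why the fit is untrustworthy.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NormalizationError(CGTensionError, ValueError):
    """Control group unusable for fold-change normalization."""


class ModelConfigurationError(CGTensionError, RuntimeError):
    """The feedback model has no fixed point in the scanned bracket."""


class IntegrationError(CGTensionError, RuntimeError):
    """The ODE integrator produced a non-finite state."""
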