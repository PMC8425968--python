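"""Exception types shared across the package."""


class RingWMError(Exception):
    """Base class for package errors."""


class ConstructionError(RingWMError):
    """A required synaptic weight-table cell is missing or invalid."""


class TopologyError(RingWMError):
    """The wiring map violates a structural anchor."""


class IntegrationError(RingWMError):
    """Numerical instability during network integration.

    Carries the offending time (ms) and neuron index.
    """

    def __init__(self, message: str, time_ms: float | None = None, neuron: int | None = None):
        super().__init__(message)
        self.time_ms = time_ms
        self.neuron = neuron


class MetricUndefinedError(RingWMError):
    """A metric is undefined on the given input (e.g., FWHM with no bump)."""


class FitError(RingWMError):
    """Degenerate input to a curve fit."""
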