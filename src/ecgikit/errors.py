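"""Exception hierarchy shared across the pipeline."""


class EcgiKitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EcgiKitError, ValueError):
    """A parameter violates its documented precondition."""


class GeometryError(EcgiKitError):
    """Invalid mesh/electrode geometry (non-watertight, out of range, ...)."""


class SignalError(EcgiKitError):
    """Recording or waveform violates a signal-processing precondition."""


class InsufficientBeatsError(SignalError):
    """Fewer beats detected than required for averaging."""


class InverseSolverError(EcgiKitError):
    """Forward/inverse operator construction or solve failed."""


class MarkerError(EcgiKitError):
    """Marker extraction failed (flat window, invalid interval, ...)."""


class StatsError(EcgiKitError):
    """A statistical routine received inadequate input."""


class PipelineError(EcgiKitError):
    """A pipeline stage aborted; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
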