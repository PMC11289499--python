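"""Exception types used across the package."""


class SimfocusError(Exception):
    """Base class for package errors."""


class ConfigurationError(SimfocusError):
    """Invalid optical configuration or inconsistent geometry."""


class SamplingError(SimfocusError):
    """Simulation grid cannot represent the requested optics."""


class DecompositionError(SimfocusError):
    """Lateral orders of the excitation pattern cannot be separated."""


class SeparationError(SimfocusError):
    """Phase-step mixing matrix is rank deficient."""


class RetrievalError(SimfocusError):
    """Offset retrieval failed (empty overlap support, mismatched inputs...)."""


class PlacementError(SimfocusError):
    """Could not place the requested beads with the given minimum separation."""
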