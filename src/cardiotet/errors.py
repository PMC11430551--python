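"""Exception hierarchy for cardiotet."""


class CardiotetError(Exception):
    """Base class for all cardiotet errors."""


class MeshParseError(CardiotetError):
    """A mesh file could not be parsed; the message names the offending line."""


class MeshValidationError(CardiotetError):
    """Mesh contents violate a structural invariant (e.g. vertex index out of range)."""


class DegenerateGeometryError(CardiotetError):
    """Two neighboring nodes coincide, so a distance-based weight is undefined."""


class NumericStateError(CardiotetError):
    """A cell-state array contains a non-finite value."""


class SimulationDivergedError(CardiotetError):
    """The integration produced non-finite or implausibly large voltages."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"simulation diverged at step {step}")
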