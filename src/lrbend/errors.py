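"""Exception types shared across the simulator and the statistics layer."""


class DegenerateGeometryError(ValueError):
    """A geometric primitive collapsed (coincident endpoints, non-positive cell area)."""


class NumericalBlowupError(RuntimeError):
    """Time integration produced non-finite coordinates."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class NonConvergenceError(RuntimeError):
    """Mechanical relaxation did not reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class InvalidStateError(RuntimeError):
    """Operation called on a tissue whose state violates its precondition."""
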