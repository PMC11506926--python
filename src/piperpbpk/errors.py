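"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when a physically or statistically invalid input is supplied."""


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries a state snapshot."""

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state
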