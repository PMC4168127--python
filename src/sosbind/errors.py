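"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


class AttemptsExhaustedError(RuntimeError):
    """The SOS acceptance loop hit its attempt cap before synthesizing the
    requested number of samples (CLI exit code 3).

    Carries the observed acceptance rate and the confidence interval so the
    caller can decide whether to widen the interval.
    """

    def __init__(self, message: str, *, acceptance_rate: float, interval: tuple):
        super().__init__(message)
        self.acceptance_rate = acceptance_rate
        self.interval = interval
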