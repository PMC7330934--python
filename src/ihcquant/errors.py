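"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class PackingError(RuntimeError):
    """Raised when the synthetic scene generator cannot place all objects."""

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved
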