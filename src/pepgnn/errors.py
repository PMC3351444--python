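"""Exception types shared across the package."""


class PepGNNError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PepGNNError, ValueError):
    """An argument violates a documented precondition."""


class UnknownResidueError(InvalidInputError):
    """A sequence character cannot be resolved in the governing alphabet.

    Carries the 1-based position of the offending character.
    """

    def __init__(self, char: str, position: int, message: str | None = None):
        self.char = char
        self.position = position
        super().__init__(
            message
            or f"unknown residue {char!r} at position {position} (1-based)"
        )


class ModelMismatchError(PepGNNError, ValueError):
    """A model and a peptide (or two models) disagree on the alphabet."""
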