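"""Exception hierarchy shared across the package."""


class PulmonarxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PulmonarxError, ValueError):
    """Malformed or physically impossible input data."""


class InsufficientDataError(PulmonarxError, ValueError):
    """Not enough usable samples / PEEP steps for the requested operation."""


class SolverError(PulmonarxError, RuntimeError):
    """The implicit pressure solve failed to bracket a root.

    ``divergence`` records which way the balance failed: ``"high"`` when
    the elastance term exceeds pressure throughout the search range (the
    model predicts off-scale-high pressure), ``"low"`` for the opposite.
    """

    def __init__(
        self,
        message: str,
        sample_index: int | None = None,
        divergence: str | None = None,
    ):
        super().__init__(message)
        self.sample_index = sample_index
        self.divergence = divergence


class InvalidPatientError(InvalidInputError):
    """Virtual-patient mechanics are unphysical (e.g. non-positive elastance)."""
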