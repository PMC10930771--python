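"""Exception taxonomy for the magnet package."""


class MagnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidRequestError(MagnetError, ValueError):
    """A pyramid/region request violates its preconditions."""


class FormatError(MagnetError, ValueError):
    """Input data has the wrong shape, dtype, or layout."""


class ContractError(MagnetError, ValueError):
    """An internal value violates a documented invariant."""


class GenerationError(MagnetError, RuntimeError):
    """Synthetic data generation could not satisfy its constraints."""


class TrainingError(MagnetError, RuntimeError):
    """Training aborted (e.g. non-finite loss)."""
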