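"""Exception types shared across the toolkit."""


class CleavekitError(Exception):
    """Base class for all cleavekit errors."""


class ConfigurationError(CleavekitError, ValueError):
    """A parameter or option is invalid (bad weights, unknown adduct, ...)."""


class InputError(CleavekitError, ValueError):
    """Input data violates a precondition (odd library size, unknown compound, ...)."""


class InfeasibleDesignError(CleavekitError, RuntimeError):
    """Pool design could not satisfy its constraints after all restarts."""

    def __init__(self, message: str, conflict_clique=None):
        super().__init__(message)
        self.conflict_clique = tuple(conflict_clique or ())


class UndefinedDistanceError(CleavekitError, ValueError):
    """A pairwise distance is undefined (no shared measured conditions)."""


class ExtinctionError(CleavekitError, RuntimeError):
    """All selection weights vanished in some round."""

    def __init__(self, message: str, round_index: int | None = None):
        super().__init__(message)
        self.round_index = round_index
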