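"""Exception hierarchy shared across the package."""


class LfpStatesError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LfpStatesError, ValueError):
    """A parameter violates its contract (size, range, ordering)."""


class UnknownStateError(LfpStatesError, KeyError):
    """A state label is not part of the declared state set."""


class InvalidConfigError(LfpStatesError, ValueError):
    """A configuration object or file is inconsistent; carries the offending key."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message if key is None else f"{message} (key: {key})")
        self.key = key


class IncompatibleGridError(LfpStatesError, ValueError):
    """Spectrograms with mismatched frequency grids cannot be pooled."""


class DegenerateReferenceError(LfpStatesError, ValueError):
    """A reference spectrum has an all-zero frequency bin."""


class EmptySelectionError(LfpStatesError, ValueError):
    """A time/window selection matched nothing."""


class InsufficientDataError(LfpStatesError, ValueError):
    """Not enough observations (subjects, dwells, escape events) for the estimator."""


class UnstableStepError(LfpStatesError, ValueError):
    """The integration time step fails the stability check."""
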