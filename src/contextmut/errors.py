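"""Exception hierarchy shared across the package."""


class ContextmutError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ContextmutError, ValueError):
    """An input file violates its declared format."""


class DetectionError(ContextmutError, RuntimeError):
    """Skew-based origin/terminus detection failed (e.g. flat profile)."""


class ConfigurationError(ContextmutError, ValueError):
    """A run was configured inconsistently (bad mode, missing prerequisite)."""


class ParameterError(ContextmutError, ValueError):
    """A synthetic-fixture request is infeasible or out of range."""


class DomainError(ContextmutError, ValueError):
    """An argument falls outside the operation's domain (bad base, bad position)."""


class ScalingError(ContextmutError, ValueError):
    """Display scaling cannot be applied (e.g. mean of rates is zero)."""


class ContextUnavailable(ContextmutError, ValueError):
    """A variant's local context cannot be resolved (N base, linear terminus)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
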