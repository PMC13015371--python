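"""Exception hierarchy shared across the package."""


class NpcscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NpcscreenError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class MatchingError(NpcscreenError, KeyError):
    """No matched untreated wells for a treated well (plate/line lookup)."""


class AlignmentError(NpcscreenError, ValueError):
    """Time grids of traces that must be compared do not coincide."""


class ValidityError(NpcscreenError, ValueError):
    """An operation was asked to use a replicate summary marked invalid."""


class DesignError(NpcscreenError, ValueError):
    """The experimental design does not support the requested analysis."""


class DomainError(NpcscreenError, ValueError):
    """A numeric argument lies outside the mathematical domain (e.g. k <= 0)."""


class UndefinedStatisticError(NpcscreenError, ValueError):
    """A statistic is undefined on this input (e.g. zero-variance correlation)."""


class SchemaError(NpcscreenError, ValueError):
    """A tabular input is missing required columns."""


class IntegrityError(NpcscreenError, ValueError):
    """A tabular input violates an integrity constraint (e.g. duplicate gene)."""


class SignAmbiguityError(NpcscreenError, ValueError):
    """A fold change of exactly zero has no direction."""
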