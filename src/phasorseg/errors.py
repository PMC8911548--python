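"""Exception hierarchy.

All package errors derive from :class:`PhasorSegError` so callers (and the
CLI) can distinguish data/runtime problems from usage/domain problems.
"""


class PhasorSegError(Exception):
    """Base class for all phasorseg errors."""


class ConfigurationError(PhasorSegError, ValueError):
    """Invalid acquisition or run configuration."""


class DomainError(PhasorSegError, ValueError):
    """Argument outside its mathematical/physical domain."""


class FormatError(PhasorSegError, ValueError):
    """Malformed input file (decay map, config, summary CSV)."""


class UndefinedPhasorError(DomainError):
    """Phasor transform requested for an all-zero decay."""


class EmptyCloudError(PhasorSegError, RuntimeError):
    """No pixel survived the peak-count filter; nothing to cluster."""


class InsufficientDataError(PhasorSegError, RuntimeError):
    """Too few phasors for the requested number of mixture components."""


class DegenerateDataError(PhasorSegError, RuntimeError):
    """All phasors identical; a mixture fit is not identifiable."""


class IntegrityError(PhasorSegError, RuntimeError):
    """Internal consistency violated (e.g. duplicate pixel back-references)."""
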