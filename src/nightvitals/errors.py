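"""Exception hierarchy for the nightvitals pipeline."""


class NightVitalsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NightVitalsError):
    """A simulation or run configuration violates its invariants."""


class InputError(NightVitalsError):
    """Malformed input data (unsorted timestamps, grid mismatch, ...)."""


class InsufficientDataError(NightVitalsError):
    """Too few observations for the requested statistic."""


class UndefinedResultError(NightVitalsError):
    """The statistic is mathematically undefined for this input."""


class AlignmentError(NightVitalsError):
    """Clock alignment is impossible (e.g. no overlapping support)."""


class CohortFormatError(NightVitalsError):
    """A serialized cohort directory is missing files or has the wrong schema."""
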