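"""Exception hierarchy for the thymixer pipeline.

Every stage raises a distinct subclass of :class:`ThymixerError` so that
callers (and the CLI, which maps them to exit codes) can tell configuration
mistakes, degenerate inputs and hard integrity failures apart.
"""


class ThymixerError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ThymixerError, ValueError):
    """Invalid configuration or generator parameters."""


class EmptyCohortError(ThymixerError, ValueError):
    """A cohort with zero patients was requested or supplied."""


class FormatError(ThymixerError, ValueError):
    """An input file or directory violates the expected on-disk format."""


class DegenerateVolumeError(ThymixerError, ValueError):
    """A volume that cannot be normalized (e.g. constant intensity under min-max)."""


class EmptyVolumeError(ThymixerError, ValueError):
    """Every slice of a volume was removed by filtering."""


class SizeError(ThymixerError, ValueError):
    """An image is too small for the requested geometric operation."""


class InsufficientSlicesError(ThymixerError, ValueError):
    """Fewer slices than required for triplet fusion."""


class StratificationError(ThymixerError, ValueError):
    """Stratified fold construction is impossible (k exceeds a class count)."""


class EmptyTaskError(ThymixerError, ValueError):
    """Task selection produced no patients (e.g. stage 2 on a thymoma-free cohort)."""


class LeakageError(ThymixerError, RuntimeError):
    """A patient contributes data to both the training and the test side of a fold."""


class NoPatchesError(ThymixerError, ValueError):
    """A scan-level decision was requested for an empty patch list."""
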