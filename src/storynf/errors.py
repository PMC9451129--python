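"""Exception hierarchy for the simulation pipeline.

Every stage raises a subclass of :class:`StorynfError` so callers can
distinguish pipeline failures from programming errors; invalid arguments
use plain :class:`ValueError` where the mistake is local.
"""


class StorynfError(Exception):
    """Base class for pipeline errors."""


class DegenerateNormsError(StorynfError):
    """Pilot normalization is unusable (sigma == 0 for some station).

    A zero pilot SD would make the score transformation divide by zero;
    this must surface loudly rather than silently returning 0.5.
    """


class TimelineError(StorynfError):
    """A station's analyzed or feedback window falls outside the run."""


class TrainingError(StorynfError):
    """A station's training data cannot support a two-class fit."""


class UndefinedDecodingAccuracyError(StorynfError):
    """A participant never chose one of the two probe labels, so the
    probe-conditioned p(c) difference is undefined."""
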