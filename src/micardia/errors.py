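"""Exception hierarchy.

Every error raised on bad user input derives from :class:`MicardiaError` so
callers can catch the package's failures without catching programming bugs.
"""


class MicardiaError(Exception):
    """Base class for all errors raised by micardia."""


class ParameterError(MicardiaError, ValueError):
    """A parameter value violates its documented constraints."""


class FormatError(MicardiaError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ChannelMissingError(FormatError):
    """A required channel is absent from a recording."""


class MontageError(MicardiaError, ValueError):
    """A Laplacian derivation is ill-defined for the given montage."""


class InsufficientDataError(MicardiaError, ValueError):
    """Too few trials/beats/samples for the requested computation."""


class EmptyEpochsError(InsufficientDataError):
    """Event selection produced no epochs."""


class NoBeatsDetectedError(MicardiaError, RuntimeError):
    """The QRS detector found no plausible beats."""


class AllTrialsRejectedError(MicardiaError, RuntimeError):
    """Artifact rejection removed every trial of a condition."""


class AlignmentError(MicardiaError, ValueError):
    """Two time courses do not share a time axis / reference convention."""


class PairingError(MicardiaError, ValueError):
    """Paired statistics received unpaired or mismatched inputs."""
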