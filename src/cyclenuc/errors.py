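"""Exception hierarchy for cyclenuc."""


class CycleNucError(Exception):
    """Base class for all cyclenuc errors."""


class ConfigError(CycleNucError):
    """Invalid configuration; the message names the violated invariant."""


class TrackError(CycleNucError):
    """Malformed nucleosome track input or out-of-bounds access."""


class NormalizationError(CycleNucError):
    """Track cannot be (re-)normalized."""


class ExpressionError(CycleNucError):
    """Malformed or degenerate expression time-course data."""


class MotifParseError(CycleNucError):
    """Invalid bracket-consensus pattern."""


class AlignmentIntegrityError(CycleNucError):
    """Degapped alignment disagrees with the stored upstream sequence."""


class ProfileError(CycleNucError):
    """Degenerate profile-matrix operation (empty group, missing rows)."""


class ValidationError(CycleNucError):
    """Fatal problem discovered while validating pipeline inputs."""
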