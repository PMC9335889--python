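"""Exception and warning types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter set is internally inconsistent or incompatible with the data."""


class CalibrationError(RuntimeError):
    """The calibration recordings cannot yield a usable rest/max contrast."""


class ProtocolError(RuntimeError):
    """An input stream violates the experimental protocol it claims to follow."""


class SessionParseError(ValueError):
    """A serialized session file is malformed; message names the offending line."""


class AdaptationWarning(UserWarning):
    """A boundary fit fell back to a default or a degenerate case was patched."""


class OrphanFeedbackWarning(UserWarning):
    """A feedback event could not be linked to any preceding motor command."""


class FeedbackLagWarning(UserWarning):
    """A feedback event was linked to a command further back than the QC lag."""
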