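"""Exception types raised by fuzzymotion."""


class FuzzymotionError(ValueError):
    """Base class for all validation errors raised by this package."""


class CalibrationError(FuzzymotionError):
    """Invalid calibration constants or an unusable calibration recording."""


class RuleTableError(FuzzymotionError):
    """Malformed, incomplete, or inconsistent rule table."""


class StreamError(FuzzymotionError):
    """Misaligned or malformed decision/ground-truth streams."""
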