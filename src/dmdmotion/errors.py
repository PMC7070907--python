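"""Exception hierarchy for dmdmotion."""


class DMDMotionError(Exception):
    """Base class for all dmdmotion errors."""


class InvalidInputError(DMDMotionError, ValueError):
    """Input data violates a documented precondition."""


class InvalidDelayError(InvalidInputError):
    """Requested delay count is outside the admissible window range."""


class DegenerateSpectrumError(DMDMotionError, ArithmeticError):
    """All eigenvalues of the reduced operator fall below the modulus tolerance."""


class ConfigError(DMDMotionError, ValueError):
    """Experiment configuration violates an invariant."""


class ParseError(DMDMotionError, ValueError):
    """Motion CSV could not be parsed; message carries the offending line."""
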