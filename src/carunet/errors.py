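"""Exception types shared across the package."""


class CarunetError(Exception):
    """Base class for package errors."""


class ConfigurationError(CarunetError, ValueError):
    """An invalid configuration value; the message names the field."""


class ShapeError(CarunetError, ValueError):
    """Incompatible array shapes."""


class CalibrationError(CarunetError, ValueError):
    """No architecture configuration reaches the requested parameter window."""


class DivergenceError(CarunetError, RuntimeError):
    """Training produced a non-finite loss."""
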