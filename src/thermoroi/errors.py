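"""Exception and warning types shared across the processing chain."""


class ThermoRoiError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ThermoRoiError):
    """A file's structure is invalid (ragged grid, missing mesh attributes...)."""


class ParseError(FormatError):
    """A token inside an otherwise structured file could not be parsed."""


class ValidationError(ThermoRoiError):
    """A value violates a domain invariant (sensor range, empty region...)."""


class ParameterError(ThermoRoiError):
    """A user-supplied parameter is outside its admissible range."""


class DegenerateFrameError(ThermoRoiError):
    """The temperature grid is constant: there is no contrast to segment."""


class GeometryError(ThermoRoiError):
    """Image geometry is inconsistent (crop window larger than the scene...)."""


class ConfigurationError(ThermoRoiError):
    """A run configuration is incomplete or self-contradictory."""


class EmptyRoIWarning(UserWarning):
    """Issued when a frame yields no region of interest; batch runs continue."""
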