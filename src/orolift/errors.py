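"""Exception hierarchy for orolift."""


class OroliftError(Exception):
    """Base class for all orolift errors."""


class InvalidParameterError(OroliftError, ValueError):
    """A scalar parameter violates its precondition (e.g. non-positive width)."""


class GridError(OroliftError, ValueError):
    """An elevation grid is malformed or an index falls outside it."""


class DegenerateFactorError(OroliftError, ArithmeticError):
    """A multiplicative adjustment factor became non-positive where it is divided."""


class RasterFormatError(OroliftError, IOError):
    """A raster file cannot be parsed or violates format preconditions."""


class UnitsError(RasterFormatError):
    """Raster coordinates are not in a projected, metre-unit system."""
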