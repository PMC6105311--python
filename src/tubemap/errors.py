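"""Exception hierarchy."""


class TubemapError(Exception):
    """Base class for all tubemap errors."""


class CalibrationError(TubemapError):
    """Missing or invalid physical calibration (spacing, units)."""


class DomainError(TubemapError):
    """Geometry falls outside the image domain, or is degenerate."""


class FitError(TubemapError):
    """Circle fitting failed (empty search grid, quality below floor)."""


class SeriesError(TubemapError):
    """Invalid or empty time series."""


class ContourError(TubemapError):
    """Invalid polygon contour (too few vertices, self-intersection, wider than the circumference)."""
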