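"""Exception hierarchy.

Everything derives from :class:`NMJQuantError` so callers can catch the
package's failures with one clause; the subclasses mirror the distinct
failure contracts of the measurement stages.
"""


class NMJQuantError(Exception):
    """Base class for all nmjquant errors."""


class ValidationError(NMJQuantError, ValueError):
    """Inputs violate a documented precondition or invariant."""


class DimensionError(ValidationError):
    """Channel volumes (or masks and volumes) disagree in shape."""


class CalibrationError(ValidationError):
    """Non-positive or inconsistent physical calibration."""


class PlacementError(NMJQuantError, RuntimeError):
    """Synthetic bouton geometry could not be placed on the canvas."""


class SaturationError(NMJQuantError, RuntimeError):
    """Requested puncta density too high for the minimum-spacing rule."""


class InsufficientDataError(ValidationError):
    """Too few observations for a statistical fit."""


class BackgroundError(NMJQuantError, RuntimeError):
    """No pixels available to estimate the image background."""


class NormalizationError(NMJQuantError, ZeroDivisionError):
    """Control-group mean is zero or the control group is empty."""
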