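"""Exception and warning types shared across the package."""


class MatBGCError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MatBGCError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(MatBGCError, ValueError):
    """A data file does not conform to the expected dialect.

    The message names the offending field or column.
    """


class ScaleMismatchError(MatBGCError, ValueError):
    """An isotope series is on the wrong scale (delta vs atom fraction)."""


class InfeasibleRatioError(MatBGCError, ValueError):
    """An observed S_tot:O2 consumption ratio lies outside the window
    attainable by mixing the incomplete- and complete-oxidation end members.

    Carries the nearest feasible end member so callers can report it; this is
    the computational counterpart of the condition under which sulfur-oxidizing
    bacteria can no longer match the flux stoichiometry imposed by their
    environment and migrate instead.
    """

    def __init__(self, ratio: float, nearest: str):
        self.ratio = ratio
        self.nearest = nearest
        super().__init__(
            f"S_tot:O2 consumption ratio {ratio:g} is outside the feasible "
            f"end-member window [2/3, 2.5]; nearest feasible end member: {nearest}"
        )


class NumericalFailureError(MatBGCError, RuntimeError):
    """A linear solve or time integration failed (singular system, blow-up)."""


class UndefinedStatisticError(MatBGCError, ValueError):
    """A statistic is undefined for the given data (e.g. non-positive
    denominator in a relative-rate normalization)."""


class MatBGCWarning(UserWarning):
    """Base warning class."""


class SensorClipWarning(MatBGCWarning):
    """Small negative sensor readings were clipped to zero."""


class FitQualityWarning(MatBGCWarning):
    """A regression window shows detectable lack of fit (curvature)."""
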