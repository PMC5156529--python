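"""Stature and body-mass estimation from footprint dimensions.

Three stature methods and three mass methods are implemented:

stature
  1. foot:stature ratio for modern H. sapiens (feet are ~14-16 % of
     stature), giving an interval estimate;
  2. walk-only linear regression of stature on footprint length
     (modern Daasanach calibration; coefficients configurable, defaults
     recovered from the packaged printed tables, SEE = 5.4 cm);
  3. foot:stature ratio for Au. afarensis (0.155-0.162).

body mass
  1. walk-only regression of mass on footprint area
     (length x max width, SEE = 3.7 kg);
  2. walk-only regression of mass on footprint length (SEE = 3.8 kg),
     used instead of the area regression when the max width is
     unreliable (e.g. the single S2 print with its enlarged anterior);
  3. foot length : mass ratio for Au. afarensis (0.543-0.632 cm/kg).

Footprint length stands in for foot length throughout, mirroring how the
ratios are applied in the trackway literature; the known footprint/foot
length bias is a documented caveat, not a correction.

All estimators are affine in footprint length (or area), so averaging
per-footprint estimates over a trackway equals estimating at the mean
footprint dimensions; both routes are exposed and agree to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._util import InvalidArgumentError, round_half_away
from .morphometry import TrackwaySummary

MM_PER_CM = 10.0

PREDICTOR_KINDS = ("footprint_length_mm", "footprint_area_mm2", "stride_over_length")


@dataclass(frozen=True)
class Interval:
    low: float
    high: float

    def __post_init__(self):
        if not (self.low <= self.high):
            raise InvalidArgumentError(f"interval low {self.low} > high {self.high}")


@dataclass(frozen=True)
class EstimatorConstants:
    """Published ratio intervals used by the ratio estimators."""

    hs_foot_stature_ratio: Interval = Interval(0.14, 0.16)     # dimensionless
    aa_foot_stature_ratio: Interval = Interval(0.155, 0.162)   # dimensionless
    aa_footlength_mass_ratio: Interval = Interval(0.543, 0.632)  # cm per kg


@dataclass(frozen=True)
class RegressionSpec:
    """An affine estimator y = intercept + slope * x with its SEE."""

    predictor: str
    slope: float
    intercept: float
    see: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.predictor not in PREDICTOR_KINDS:
            raise InvalidArgumentError(
                f"unknown predictor kind {self.predictor!r}; expected one of {PREDICTOR_KINDS}")
        if self.see < 0:
            raise InvalidArgumentError("SEE must be non-negative")


@dataclass
class RangeEstimate:
    low: float
    high: float
    units: str
    method: str

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    def rounded(self, ndigits: int = 0) -> "RangeEstimate":
        return RangeEstimate(
            low=round_half_away(self.low, ndigits),
            high=round_half_away(self.high, ndigits),
            units=self.units, method=self.method)


@dataclass
class PointEstimate:
    value: float
    see: float
    units: str
    method: str


@dataclass
class BodyProfile:
    """Stature and mass estimates, per method, for one individual."""

    individual_id: str
    stature_by_method: dict = field(default_factory=dict)
    mass_by_method: dict = field(default_factory=dict)
    n_footprints_used: int = 0
    flags: list = field(default_factory=list)


def stature_from_ratio(footprint_length_mm: float, ratio: Interval,
                       method: str = "foot_stature_ratio") -> RangeEstimate:
    """Stature interval (cm) from a foot:stature ratio interval.

    A small ratio means a small foot on a tall body, so the ratio upper
    bound gives the stature lower bound and vice versa.
    """
    if footprint_length_mm <= 0:
        raise InvalidArgumentError("footprint length must be positive")
    if not (0 < ratio.low <= ratio.high < 1):
        raise InvalidArgumentError("foot:stature ratio interval must lie in (0, 1)")
    length_cm = footprint_length_mm / MM_PER_CM
    return RangeEstimate(low=length_cm / ratio.high, high=length_cm / ratio.low,
                         units="cm", method=method)


def mass_from_ratio(footprint_length_mm: float, ratio: Interval,
                    method: str = "aa_footlength_mass_ratio") -> RangeEstimate:
    """Body-mass interval (kg) from a foot length (cm) : mass (kg) ratio."""
    if footprint_length_mm <= 0:
        raise InvalidArgumentError("footprint length must be positive")
    if ratio.low <= 0:
        raise InvalidArgumentError("ratio interval must be positive")
    length_cm = footprint_length_mm / MM_PER_CM
    return RangeEstimate(low=length_cm / ratio.high, high=length_cm / ratio.low,
                         units="kg", method=method)


def predict_linear(x: float, spec: RegressionSpec, predictor: Optional[str] = None):
    """Evaluate an affine regression; returns (point estimate, SEE)."""
    if predictor is not None and predictor != spec.predictor:
        raise InvalidArgumentError(
            f"predictor mismatch: value is {predictor!r} but spec expects {spec.predictor!r}")
    return spec.intercept + spec.slope * x, spec.see


def profile_individual(summary: TrackwaySummary,
                       constants: EstimatorConstants,
                       specs: dict,
                       s2_exception: bool = False) -> BodyProfile:
    """All stature and mass estimates for one individual.

    *specs* maps {"stature_by_length", "mass_by_area", "mass_by_length"}
    to RegressionSpec.  When *s2_exception* is set (or the summary flags
    its widths as overestimated) the area regression is replaced by the
    length regression for mass, because the recorded max width does not
    reflect the foot.

    Because every estimator is affine in footprint length (or area),
    evaluating at the summary means equals averaging per-footprint
    estimates; this function evaluates at the means.
    """
    if summary.length_mean is None:
        raise InvalidArgumentError(
            f"individual {summary.individual_id!r}: no footprint lengths to estimate from")

    L = summary.length_mean
    profile = BodyProfile(individual_id=summary.individual_id,
                          n_footprints_used=summary.n_measurable)

    profile.stature_by_method["hs_ratio"] = stature_from_ratio(
        L, constants.hs_foot_stature_ratio, method="hs_ratio")
    profile.stature_by_method["aa_ratio"] = stature_from_ratio(
        L, constants.aa_foot_stature_ratio, method="aa_ratio")
    if "stature_by_length" in specs:
        value, see = predict_linear(L, specs["stature_by_length"], "footprint_length_mm")
        profile.stature_by_method["hs_regression"] = PointEstimate(
            value=value, see=see, units="cm", method="hs_regression")

    profile.mass_by_method["aa_ratio"] = mass_from_ratio(
        L, constants.aa_footlength_mass_ratio, method="aa_ratio")

    use_length_reg = s2_exception or summary.width_overestimated
    if use_length_reg:
        profile.flags.append("mass regression on length: max width unreliable")
        if "mass_by_length" in specs:
            value, see = predict_linear(L, specs["mass_by_length"], "footprint_length_mm")
            profile.mass_by_method["hs_regression"] = PointEstimate(
                value=value, see=see, units="kg", method="hs_regression_length")
    else:
        if "mass_by_area" in specs:
            if summary.width_mean is None:
                raise InvalidArgumentError(
                    f"individual {summary.individual_id!r}: area regression requested "
                    "but no widths available and no exception flag set")
            # prefer the mean of per-footprint areas (the estimator is affine
            # in area, so this equals averaging per-print estimates); fall
            # back to the product of means when only summary values exist
            area = summary.area_mean if summary.area_mean is not None \
                else L * summary.width_mean
            value, see = predict_linear(area, specs["mass_by_area"], "footprint_area_mm2")
            profile.mass_by_method["hs_regression"] = PointEstimate(
                value=value, see=see, units="kg", method="hs_regression_area")
    return profile
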