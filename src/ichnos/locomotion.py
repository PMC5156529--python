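"""Walking-speed and relative-speed estimation.

Two methods are implemented:

* the dynamic-similarity power law of Alexander (1976),

      v = 0.25 * g^0.5 * L^1.67 * h^-1.17,

  with v walking speed (m/s), g gravitational acceleration (m/s^2),
  L stride length (m) and h stature (m).  Geometrically similar walkers
  moving with equal Froude number v^2/(g h) trace it out; scaling L and
  h by k scales v by k^0.5.

* a walk-only linear regression of speed on the ratio stride length /
  mean footprint length (modern human calibration; coefficients
  configurable, defaults recovered from the packaged printed tables).

Relative speed is walking speed divided by stature (1/s), a
size-independent gait comparator.  Both methods are meant for walking
gaits only: the walk-to-run transition sits around 2.2 m/s, and any
estimate above it is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._util import InvalidArgumentError
from .bodysize import RangeEstimate, RegressionSpec, predict_linear
from .morphometry import TrackwaySummary

G_DEFAULT = 9.81  # m/s^2
WALK_RUN_TRANSITION = 2.2  # m/s


@dataclass(frozen=True)
class SpeedInputs:
    stride_length_m: float
    stature_m: float
    gravity: float = G_DEFAULT

    def __post_init__(self):
        if self.stride_length_m <= 0 or self.stature_m <= 0 or self.gravity <= 0:
            raise InvalidArgumentError("stride, stature and gravity must be positive")


@dataclass
class SpeedEstimate:
    method: str                       # "alexander1976" | "regression_walk"
    speed: object                     # float or (low, high)
    relative_speed: object            # float or (low, high)
    above_walk_run_transition: bool = False
    notes: list = field(default_factory=list)


def alexander_speed(inp: SpeedInputs) -> float:
    """Walking speed (m/s) from the dynamic-similarity power law."""
    return 0.25 * inp.gravity ** 0.5 * inp.stride_length_m ** 1.67 \
        * inp.stature_m ** -1.17


def regression_speed(stride_mm: float, mean_footprint_length_mm: float,
                     spec: RegressionSpec) -> float:
    """Walking speed (m/s) from the stride/footprint-length regression."""
    if stride_mm <= 0 or mean_footprint_length_mm <= 0:
        raise InvalidArgumentError("stride and footprint length must be positive")
    ratio = stride_mm / mean_footprint_length_mm
    value, _ = predict_linear(ratio, spec, "stride_over_length")
    return value


def relative_speed(v: float, stature_m: float) -> float:
    """Walking speed / stature (1/s)."""
    if stature_m <= 0:
        raise InvalidArgumentError("stature must be positive")
    return v / stature_m


def speed_profile(summary: TrackwaySummary,
                  stature_range_cm: RangeEstimate,
                  spec: Optional[RegressionSpec] = None,
                  regression_stature_cm: Optional[float] = None,
                  gravity: float = G_DEFAULT) -> list:
    """Both speed estimates for one trackway.

    The power-law speed is an interval over the stature range: v falls
    with stature, so the tallest stature gives the slowest bound and
    vice versa.  Each relative-speed bound divides a speed bound by the
    stature that produced it.  The regression speed is a point value
    whose relative speed uses *regression_stature_cm* (the regression
    stature estimate) when given.
    """
    if summary.stride_mean is None:
        raise InvalidArgumentError(
            f"individual {summary.individual_id!r}: no stride data, cannot estimate speed")
    L_m = summary.stride_mean / 1000.0
    h_low = stature_range_cm.low / 100.0
    h_high = stature_range_cm.high / 100.0

    v_slow = alexander_speed(SpeedInputs(L_m, h_high, gravity))
    v_fast = alexander_speed(SpeedInputs(L_m, h_low, gravity))
    alex = SpeedEstimate(
        method="alexander1976",
        speed=(v_slow, v_fast),
        relative_speed=(relative_speed(v_slow, h_high), relative_speed(v_fast, h_low)),
        above_walk_run_transition=v_fast > WALK_RUN_TRANSITION,
    )
    if alex.above_walk_run_transition:
        alex.notes.append("speed above the ~2.2 m/s walk-to-run transition; "
                          "walk-only calibration not applicable")
    out = [alex]

    if spec is not None:
        if summary.length_mean is None:
            raise InvalidArgumentError(
                f"individual {summary.individual_id!r}: no footprint length for speed regression")
        v = regression_speed(summary.stride_mean, summary.length_mean, spec)
        h_reg = (regression_stature_cm / 100.0) if regression_stature_cm else None
        reg = SpeedEstimate(
            method="regression_walk",
            speed=v,
            relative_speed=relative_speed(v, h_reg) if h_reg else None,
            above_walk_run_transition=v > WALK_RUN_TRANSITION,
        )
        if reg.above_walk_run_transition:
            reg.notes.append("speed above the ~2.2 m/s walk-to-run transition; "
                             "walk-only calibration not applicable")
        out.append(reg)
    return out
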