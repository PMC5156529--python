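"""Footprint- and trackway-level geometric measurement.

All coordinates are planar Cartesian in millimetres, with y increasing
along the walking direction by convention.  The measures follow the
standard ichnological definitions:

* footprint length  — maximum distance between the anterior tip of the
  hallux and the posterior tip of the heel;
* footprint max width — width across the distal metatarsal (ball) region;
* foot index        — 100 x max width / length;
* step length       — heel-to-heel distance between two successive tracks;
* stride length     — heel-to-heel distance between two successive tracks
  on the same side;
* angle of gait     — angle between the trackway midline and the
  longitudinal axis of the foot.

The foot longitudinal axis is taken as the segment from the posterior heel
tip to the anterior hallux tip: these are the two landmarks the length
definition itself names, and the convention makes length and axis
self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Polygon

from ._util import (
    InsufficientLandmarksError,
    InvalidArgumentError,
    as_point,
    unit,
)

#: landmark names understood by :func:`measure_footprint`
LANDMARK_NAMES = (
    "heel_posterior_tip",
    "hallux_anterior_tip",
    "ball_medial",
    "ball_lateral",
    "heel_medial",
    "heel_lateral",
)

# caliper-window fractions of the foot length used when ball/heel landmark
# pairs are absent and widths must be taken from the outline
_BALL_WINDOW = (0.40, 1.00)   # anterior 60 %
_HEEL_WINDOW = (0.00, 0.30)   # posterior 30 %


@dataclass
class FootprintMetrics:
    """Scalar footprint measures in mm (foot_index in percent)."""

    length: float
    max_width: float
    heel_width: Optional[float] = None
    foot_index: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length is not None and self.length <= 0:
            raise InvalidArgumentError("footprint length must be positive")
        if self.max_width is not None and self.max_width <= 0:
            raise InvalidArgumentError("footprint max width must be positive")
        if self.foot_index is None and self.length and self.max_width:
            self.foot_index = 100.0 * self.max_width / self.length


@dataclass
class Footprint:
    """One track: side, optional landmarks/outline, optional metrics.

    ``gap_before`` flags a recorded gap (an indiscernible or destroyed
    print) between this footprint and its predecessor; steps and strides
    across gaps are skipped, never interpolated.
    """

    id: str
    side: str
    landmarks: Optional[dict] = None
    outline: Optional[Polygon] = None
    metrics: Optional[FootprintMetrics] = None
    gap_before: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InvalidArgumentError(
                f"footprint {self.id!r}: side must be 'left' or 'right', got {self.side!r}"
            )
        if self.landmarks is not None:
            self.landmarks = {k: as_point(v) for k, v in self.landmarks.items()}
            h = self.landmarks.get("heel_posterior_tip")
            t = self.landmarks.get("hallux_anterior_tip")
            if h is not None and t is not None and np.allclose(h, t):
                raise InvalidArgumentError(
                    f"footprint {self.id!r}: heel and hallux tips coincide"
                )
        if self.outline is not None:
            if not self.outline.is_valid or not self.outline.is_simple:
                raise InvalidArgumentError(
                    f"footprint {self.id!r}: outline must be a simple closed polygon"
                )

    def landmark(self, name: str) -> np.ndarray:
        if self.landmarks is None or name not in self.landmarks:
            raise InsufficientLandmarksError(
                f"footprint {self.id!r}: insufficient landmarks, missing {name!r}"
            )
        return self.landmarks[name]

    @property
    def heel(self) -> Optional[np.ndarray]:
        if self.landmarks is None:
            return None
        return self.landmarks.get("heel_posterior_tip")

    @property
    def foot_axis(self) -> np.ndarray:
        """Unit vector from posterior heel tip to anterior hallux tip."""
        return unit(self.landmark("hallux_anterior_tip") - self.landmark("heel_posterior_tip"))


@dataclass
class Trackway:
    """Ordered footprints of one individual, in walking order."""

    individual_id: str
    footprints: list
    heading: Optional[float] = None  # degrees, informational

    def __post_init__(self) -> None:
        if len(self.footprints) < 1:
            raise InvalidArgumentError("a trackway needs at least one footprint")

    def with_heels(self) -> list:
        return [fp for fp in self.footprints if fp.heel is not None]


@dataclass
class GaitSummary:
    step_lengths: list          # (from_id, to_id, mm)
    stride_lengths: list        # (from_id, to_id, mm)
    angles_of_gait: list        # (id, degrees)
    mean_step: Optional[float]
    mean_stride: Optional[float]
    mean_stride_by_side: dict = field(default_factory=dict)
    mean_step_by_pattern: dict = field(default_factory=dict)
    skipped_pairs: list = field(default_factory=list)


@dataclass
class TrackwaySummary:
    """Per-individual aggregation — one column of a comparative table."""

    individual_id: str
    n_measurable: int
    length_mean: Optional[float] = None
    length_sd: Optional[float] = None
    length_range: Optional[tuple] = None
    width_mean: Optional[float] = None
    width_sd: Optional[float] = None
    width_range: Optional[tuple] = None
    foot_index_mean: Optional[float] = None
    foot_index_sd: Optional[float] = None
    foot_index_range: Optional[tuple] = None
    # mean per-footprint length x width; kept separately because the mass
    # regression averages per-print areas, not the product of the means
    area_mean: Optional[float] = None
    step_mean: Optional[float] = None
    step_sd: Optional[float] = None
    step_range: Optional[tuple] = None
    stride_mean: Optional[float] = None
    stride_sd: Optional[float] = None
    stride_range: Optional[tuple] = None
    stride_mean_by_side: dict = field(default_factory=dict)
    width_overestimated: bool = False


def _caliper_width(outline: Polygon, origin: np.ndarray, axis: np.ndarray,
                   length: float, window: tuple) -> float:
    """Max outline extent perpendicular to *axis*, restricted to a
    longitudinal window (fractions of *length* measured from *origin*)."""
    perp = np.array([-axis[1], axis[0]])
    coords = np.asarray(outline.exterior.coords, dtype=float)
    t = (coords - origin) @ axis
    keep = (t >= window[0] * length - 1e-9) & (t <= window[1] * length + 1e-9)
    if keep.sum() < 2:
        raise InvalidArgumentError("outline has no vertices in the caliper window")
    w = (coords[keep] - origin) @ perp
    return float(w.max() - w.min())


def measure_footprint(footprint: Footprint, axis=None) -> FootprintMetrics:
    """Measure length, widths and foot index from landmarks (and outline).

    *axis*, if given, must be a unit vector; it orients the caliper used
    for outline-based widths.  It defaults to the foot's own longitudinal
    axis (posterior heel tip -> anterior hallux tip).
    """
    heel = footprint.landmark("heel_posterior_tip")
    hallux = footprint.landmark("hallux_anterior_tip")
    length = float(np.linalg.norm(hallux - heel))

    if axis is None:
        ax = unit(hallux - heel)
    else:
        ax = np.asarray(axis, dtype=float)
        if ax.shape != (2,):
            raise InvalidArgumentError("axis must be a 2-vector")
        n = np.linalg.norm(ax)
        if n == 0:
            raise InvalidArgumentError("axis must not be zero-length")
        if abs(n - 1.0) > 1e-6:
            raise InvalidArgumentError("axis must be normalized")

    lm = footprint.landmarks or {}
    if "ball_medial" in lm and "ball_lateral" in lm:
        max_width = float(np.linalg.norm(lm["ball_medial"] - lm["ball_lateral"]))
    elif footprint.outline is not None:
        max_width = _caliper_width(footprint.outline, heel, ax, length, _BALL_WINDOW)
    else:
        raise InsufficientLandmarksError(
            f"footprint {footprint.id!r}: insufficient landmarks, missing ball_medial/ball_lateral "
            "and no outline to fall back on"
        )

    heel_width: Optional[float] = None
    if "heel_medial" in lm and "heel_lateral" in lm:
        heel_width = float(np.linalg.norm(lm["heel_medial"] - lm["heel_lateral"]))
    elif footprint.outline is not None:
        heel_width = _caliper_width(footprint.outline, heel, ax, length, _HEEL_WINDOW)

    return FootprintMetrics(
        length=length,
        max_width=max_width,
        heel_width=heel_width,
        foot_index=100.0 * max_width / length,
    )


def trackway_midline(trackway: Trackway):
    """Total-least-squares midline of the trackway.

    The line is fitted through the midpoints of successive heel pairs
    rather than through the heels themselves: heels alternate left and
    right of the walker's path, and that stagger tilts a line fitted to
    them directly, whereas the pair midpoints cancel it.  Returns
    ``(point, direction)`` with the unit direction oriented along
    walking order.
    """
    heels = np.array([fp.heel for fp in trackway.with_heels()])
    if len(heels) < 2:
        raise InvalidArgumentError(
            f"trackway {trackway.individual_id!r}: underdetermined midline "
            f"({len(heels)} usable footprints, need >= 2)"
        )
    pts = 0.5 * (heels[:-1] + heels[1:]) if len(heels) >= 3 else heels
    centroid = pts.mean(axis=0)
    # principal axis of the centred midpoint cloud = TLS line direction
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    direction = vt[0]
    if (heels[-1] - heels[0]) @ direction < 0:
        direction = -direction
    return centroid, direction


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(np.clip(abs(u @ v), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _signed_angle_deg(axis: np.ndarray, midline: np.ndarray, side: str) -> float:
    """Signed angle of gait: positive = out-toeing (axis rotated away from
    the midline toward the footprint's own side)."""
    raw = math.degrees(math.atan2(np.cross(midline, axis), midline @ axis))
    return raw if side == "left" else -raw


def gait_metrics(trackway: Trackway, signed_angles: bool = False) -> GaitSummary:
    """Step/stride lengths and angles of gait for one trackway.

    Steps pair consecutive footprints whose heels are both present and
    with no recorded gap between them; strides pair same-side footprints
    separated by exactly one opposite-side footprint.  Pairs interrupted
    by a gap or a missing heel are skipped and reported, never
    interpolated.
    """
    fps = trackway.footprints
    if len(trackway.with_heels()) < 2:
        raise InvalidArgumentError(
            f"trackway {trackway.individual_id!r}: need >= 2 footprints with heel landmarks"
        )

    steps, strides, skipped = [], [], []
    for a, b in zip(fps, fps[1:]):
        if b.gap_before:
            skipped.append((a.id, b.id, "recorded gap"))
            continue
        if a.heel is None or b.heel is None:
            skipped.append((a.id, b.id, "missing heel landmark"))
            continue
        steps.append((a.id, b.id, float(np.linalg.norm(b.heel - a.heel))))

    for a, mid, b in zip(fps, fps[1:], fps[2:]):
        if mid.gap_before or b.gap_before:
            skipped.append((a.id, b.id, "recorded gap"))
            continue
        if a.side != b.side or mid.side == a.side:
            continue
        if a.heel is None or b.heel is None:
            skipped.append((a.id, b.id, "missing heel landmark"))
            continue
        strides.append((a.id, b.id, float(np.linalg.norm(b.heel - a.heel))))

    angles = []
    try:
        _, midline = trackway_midline(trackway)
    except InvalidArgumentError:
        midline = None
    if midline is not None:
        for fp in fps:
            if fp.landmarks and "heel_posterior_tip" in fp.landmarks \
                    and "hallux_anterior_tip" in fp.landmarks:
                if signed_angles:
                    angles.append((fp.id, _signed_angle_deg(fp.foot_axis, midline, fp.side)))
                else:
                    angles.append((fp.id, _angle_deg(fp.foot_axis, midline)))

    side_of = {fp.id: fp.side for fp in fps}
    stride_by_side: dict = {}
    for s in ("right", "left"):
        vals = [v for (f, _, v) in strides if side_of[f] == s]
        if vals:
            stride_by_side[s] = float(np.mean(vals))
    step_by_pattern: dict = {}
    for pat in (("right", "left"), ("left", "right")):
        vals = [v for (f, t, v) in steps if side_of[f] == pat[0] and side_of[t] == pat[1]]
        if vals:
            step_by_pattern["->".join(pat)] = float(np.mean(vals))

    return GaitSummary(
        step_lengths=steps,
        stride_lengths=strides,
        angles_of_gait=angles,
        mean_step=float(np.mean([v for *_, v in steps])) if steps else None,
        mean_stride=float(np.mean([v for *_, v in strides])) if strides else None,
        mean_stride_by_side=stride_by_side,
        mean_step_by_pattern=step_by_pattern,
        skipped_pairs=skipped,
    )


def _stats(values):
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else None
    return float(v.mean()), sd, (float(v.min()), float(v.max()))


def summarize_trackway(individual_id: str, metrics, gait: Optional[GaitSummary] = None,
                       width_overestimated: bool = False) -> TrackwaySummary:
    """Aggregate per-footprint metrics (and optionally gait) into the
    per-individual summary: mean, sample SD and min-max range."""
    metrics = [m for m in metrics if m is not None and m.length is not None]
    if not metrics:
        raise InvalidArgumentError(f"individual {individual_id!r}: no measurable footprints")

    out = TrackwaySummary(individual_id=individual_id, n_measurable=len(metrics),
                          width_overestimated=width_overestimated)
    out.length_mean, out.length_sd, out.length_range = _stats([m.length for m in metrics])
    widths = [m.max_width for m in metrics if m.max_width is not None]
    if widths:
        out.width_mean, out.width_sd, out.width_range = _stats(widths)
    indices = [m.foot_index for m in metrics if m.foot_index is not None]
    if indices:
        out.foot_index_mean, out.foot_index_sd, out.foot_index_range = _stats(indices)
    areas = [m.length * m.max_width for m in metrics if m.max_width is not None]
    if areas:
        out.area_mean = float(np.mean(areas))

    if gait is not None:
        if gait.step_lengths:
            out.step_mean, out.step_sd, out.step_range = _stats(
                [v for *_, v in gait.step_lengths])
        if gait.stride_lengths:
            out.stride_mean, out.stride_sd, out.stride_range = _stats(
                [v for *_, v in gait.stride_lengths])
        out.stride_mean_by_side = dict(gait.mean_stride_by_side)
    return out
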