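"""Synthetic trackways, footprint rasters and survey networks.

Every generator returns its exact ground truth alongside the synthetic
observation, so each pipeline stage can be tested round-trip without any
external data.  All randomness flows through a single integer-seeded
``numpy.random.default_rng`` generator, making output bit-reproducible.

The default parameter presets emulate the published per-trackway means
(footprint lengths ~180-274 mm, step lengths ~505-660 mm, angles of gait
roughly 2-11 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from shapely import affinity
from shapely.geometry import Point
from shapely.ops import unary_union

from ._util import InvalidArgumentError
from .dem import ElevationGrid
from .morphometry import Footprint, FootprintMetrics, Trackway
from .survey import ControlNetwork, DistanceObs, HeightObs


@dataclass(frozen=True)
class TrackwayParams:
    stature: float = 165.0            # cm
    foot_stature_ratio: float = 0.158
    step_mean: float = 568.0          # mm
    step_sd: float = 44.0             # mm
    straddle: float = 60.0            # mm, lateral heel-line separation
    angle_of_gait_mean: float = 6.0   # degrees, out-toeing positive
    angle_of_gait_sd: float = 3.0
    heading: float = 90.0             # degrees CCW from +x (90 = walking +y)
    n_footprints: int = 8
    foot_index: float = 0.40          # max width / length
    heel_width_ratio: float = 0.31    # heel width / length
    missing_ids: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.stature <= 0 or self.step_mean <= 0:
            raise InvalidArgumentError("stature and step_mean must be positive")
        if self.step_sd < 0 or self.angle_of_gait_sd < 0:
            raise InvalidArgumentError("standard deviations must be non-negative")
        if self.n_footprints < 2:
            raise InvalidArgumentError("need at least 2 footprints")
        if not (0 < self.foot_stature_ratio < 1):
            raise InvalidArgumentError("foot:stature ratio must lie in (0, 1)")


#: presets populated from the published per-trackway summary means
PRESETS = {
    "S1-like": TrackwayParams(stature=165.0, foot_stature_ratio=0.158,
                              step_mean=568.0, step_sd=44.0, foot_index=0.40),
    "G1-like": TrackwayParams(stature=114.0, foot_stature_ratio=0.158,
                              step_mean=416.0, step_sd=30.0, foot_index=0.44),
    "G2-like": TrackwayParams(stature=142.0, foot_stature_ratio=0.158,
                              step_mean=453.0, step_sd=30.0, foot_index=0.48),
    "G3-like": TrackwayParams(stature=132.0, foot_stature_ratio=0.158,
                              step_mean=433.0, step_sd=30.0, foot_index=0.42),
}


@dataclass
class GroundTruth:
    params: TrackwayParams
    heel_points: np.ndarray            # (n, 2) true heel coordinates
    landmarks: list                    # per footprint: dict or None
    metrics: list                      # per footprint: FootprintMetrics or None
    step_draws: np.ndarray             # Euclidean heel-to-heel steps as drawn
    angle_draws: np.ndarray            # per-print angle of gait, degrees
    heading_unit: np.ndarray           # unit heading vector
    foot_length: float                 # mm


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])


def _template_landmarks(length: float, width: float, heel_width: float,
                        side: str = "right") -> dict:
    """Landmark set of the footprint template, local frame (axis = +y)."""
    landmarks = {
        "heel_posterior_tip": np.array([0.0, 0.0]),
        "hallux_anterior_tip": np.array([0.0, length]),
        "ball_medial": np.array([-width / 2.0, 0.69 * length]),
        "ball_lateral": np.array([width / 2.0, 0.69 * length]),
        "heel_medial": np.array([-heel_width / 2.0, 0.15 * length]),
        "heel_lateral": np.array([heel_width / 2.0, 0.15 * length]),
    }
    if side == "left":
        landmarks = {k: np.array([-v[0], v[1]]) for k, v in landmarks.items()}
        landmarks["ball_medial"], landmarks["ball_lateral"] = \
            landmarks["ball_lateral"], landmarks["ball_medial"]
        landmarks["heel_medial"], landmarks["heel_lateral"] = \
            landmarks["heel_lateral"], landmarks["heel_medial"]
    return landmarks


def footprint_template(length: float, width: float, heel_width: float,
                       side: str = "right"):
    """Piecewise-elliptical footprint outline with its landmark set.

    Local frame: longitudinal axis along +y, posterior heel tip at the
    origin, anterior hallux tip at (0, length).  The shape is a heel
    ellipse, a midfoot waist, a forefoot (ball) lobe and an adducted
    hallux nub — the simplest outline reproducing the measured
    quantities.  ``side`` mirrors the template across the axis.
    """

    def ellipse(cx, cy, sx, sy):
        return affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=32), sx, sy)

    heel = ellipse(0.0, 0.15 * length, heel_width / 2.0, 0.15 * length)
    waist = ellipse(0.0, 0.42 * length, 0.38 * width, 0.22 * length)
    ball = ellipse(0.0, 0.70 * length, width / 2.0, 0.18 * length)
    hallux = ellipse(0.0, 0.93 * length, 0.22 * width, 0.07 * length)
    outline = unary_union([heel, waist, ball, hallux])
    if side == "left":
        outline = affinity.scale(outline, -1.0, 1.0, origin=(0, 0))
    return outline, _template_landmarks(length, width, heel_width, side)


def generate_trackway(params: TrackwayParams, with_outlines: bool = True):
    """Simulate one bipedal trackway; returns (Trackway, GroundTruth).

    ``with_outlines=False`` skips building the polygon outlines (landmark
    coordinates and every derived quantity are identical), which is much
    faster for large simulation batches.

    Heels alternate right/left of the heading line at lateral offset
    straddle/2; heel-to-heel (Euclidean) step lengths are drawn from
    N(step_mean, step_sd) truncated below at max(foot length, straddle),
    so each drawn value is exactly the step a measurer would recover.
    Per-print angles of gait are drawn from N(mean, sd) and applied as
    out-toeing away from the midline.
    """
    rng = np.random.default_rng(params.seed)
    foot_length = params.foot_stature_ratio * params.stature * 10.0  # mm
    width = params.foot_index * foot_length
    heel_width = params.heel_width_ratio * foot_length
    floor = max(foot_length, params.straddle * 1.001)
    if params.step_sd == 0 and params.step_mean <= floor:
        raise InvalidArgumentError(
            f"step_mean {params.step_mean} must exceed the truncation floor {floor:.1f}")

    n = params.n_footprints
    steps = np.empty(n - 1)
    for i in range(n - 1):
        draw = params.step_mean if params.step_sd == 0 else \
            rng.normal(params.step_mean, params.step_sd)
        while draw <= floor:
            draw = rng.normal(params.step_mean, params.step_sd)
        steps[i] = draw
    angles = np.full(n, params.angle_of_gait_mean) if params.angle_of_gait_sd == 0 \
        else rng.normal(params.angle_of_gait_mean, params.angle_of_gait_sd, size=n)
    angles = np.clip(angles, 0.0, 45.0)

    u = np.array([math.cos(math.radians(params.heading)),
                  math.sin(math.radians(params.heading))])
    nvec = np.array([-u[1], u[0]])  # walker's left

    # longitudinal advances chosen so the Euclidean step equals the draw
    sides = ["right" if i % 2 == 0 else "left" for i in range(n)]
    lateral = np.array([-params.straddle / 2.0 if s == "right" else params.straddle / 2.0
                        for s in sides])
    long_pos = np.zeros(n)
    for i, step in enumerate(steps):
        dlat = lateral[i + 1] - lateral[i]
        long_pos[i + 1] = long_pos[i] + math.sqrt(step ** 2 - dlat ** 2)
    heels = np.outer(long_pos, u) + np.outer(lateral, nvec)

    footprints, lm_truth, metric_truth = [], [], []
    for i in range(n):
        fid = f"SYN-{i + 1}"
        if i in params.missing_ids or fid in params.missing_ids:
            footprints.append(Footprint(id=fid, side=sides[i]))
            lm_truth.append(None)
            metric_truth.append(None)
            continue
        if with_outlines:
            outline, lm = footprint_template(foot_length, width, heel_width, side=sides[i])
        else:
            outline, lm = None, _template_landmarks(foot_length, width, heel_width, sides[i])
        # out-toeing rotates the foot axis away from the midline
        toe_out = angles[i] if sides[i] == "left" else -angles[i]
        R = _rot(params.heading - 90.0 + toe_out)
        world_lm = {k: heels[i] + R @ v for k, v in lm.items()}
        world_outline = None if outline is None else affinity.translate(
            affinity.rotate(outline, params.heading - 90.0 + toe_out, origin=(0, 0)),
            xoff=heels[i][0], yoff=heels[i][1])
        footprints.append(Footprint(id=fid, side=sides[i], landmarks=world_lm,
                                    outline=world_outline))
        lm_truth.append(world_lm)
        metric_truth.append(FootprintMetrics(
            length=foot_length, max_width=width, heel_width=heel_width))

    trackway = Trackway(individual_id="SYN", footprints=footprints,
                        heading=params.heading)
    truth = GroundTruth(params=params, heel_points=heels, landmarks=lm_truth,
                        metrics=metric_truth, step_draws=steps, angle_draws=angles,
                        heading_unit=u, foot_length=foot_length)
    return trackway, truth


@dataclass(frozen=True)
class DepthProfile:
    """Depression depth model: deepest at the heel, shallowing toward the
    toes, with an optional posterior heel-drag ramp (~100 mm in the best
    preserved tracks)."""

    heel_depth: float = 8.0       # mm below the reference surface
    toe_depth: float = 5.0        # mm
    drag_length: float = 0.0      # mm of posterior drag mark


def rasterize_footprint(footprint: Footprint, profile: DepthProfile = DepthProfile(),
                        spacing: float = 1.0, noise_sd: float = 0.0,
                        seed: int = 0, margin: float = 40.0,
                        base_slope: tuple = (0.0, 0.0)) -> ElevationGrid:
    """Press a footprint depression into a gently varying surface.

    The raster covers the outline (or landmark hull) plus *margin*;
    depth inside the outline interpolates linearly from heel_depth at
    the posterior tip to toe_depth at the anterior tip.  A drag ramp, if
    configured, extends the depression posteriorly, tapering to zero
    over ``drag_length``.  Seeded Gaussian micro-relief of *noise_sd* mm
    is added everywhere.
    """
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be positive")
    if footprint.outline is None:
        raise InvalidArgumentError("rasterization needs a footprint outline")
    heel = footprint.landmark("heel_posterior_tip")
    toe = footprint.landmark("hallux_anterior_tip")
    axis = (toe - heel) / np.linalg.norm(toe - heel)
    length = float(np.linalg.norm(toe - heel))

    minx, miny, maxx, maxy = footprint.outline.bounds
    if spacing > (maxx - minx) or spacing > (maxy - miny):
        raise InvalidArgumentError(
            f"under-resolved: spacing {spacing} mm exceeds the footprint extent")
    # the raster must cover the drag mark behind the heel as well
    margin = max(margin, profile.drag_length + 10.0)
    x0, y0 = minx - margin, miny - margin
    nx = int(np.ceil((maxx + margin - x0) / spacing)) + 1
    ny = int(np.ceil((maxy + margin - y0) / spacing)) + 1
    xs = x0 + spacing * np.arange(nx)
    ys = y0 + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys)

    base = base_slope[0] * gx + base_slope[1] * gy

    import shapely as _sh  # fast vectorized point-in-polygon
    inside = _sh.contains_xy(footprint.outline, gx, gy)
    t = ((np.stack([gx, gy], axis=-1) - heel) @ axis) / max(length, 1e-9)
    depth = np.where(
        inside,
        profile.heel_depth + (profile.toe_depth - profile.heel_depth) * np.clip(t, 0, 1),
        0.0,
    )
    if profile.drag_length > 0:
        # ramp behind the heel along the axis, within the heel's width
        perp = np.array([-axis[1], axis[0]])
        s = (np.stack([gx, gy], axis=-1) - heel) @ perp
        # overlap the ramp half a cell past the heel tip so the drag mark
        # stays 4-connected to the footprint depression in the raster
        behind = (t * length < 0.5 * spacing) & (t * length > -profile.drag_length) \
            & (np.abs(s) < length * 0.12)
        ramp = profile.heel_depth * (1.0 + t * length / profile.drag_length)
        depth = np.where(behind, np.maximum(depth, ramp), depth)

    z = base - depth
    if noise_sd > 0:
        z = z + np.random.default_rng(seed).normal(0.0, noise_sd, size=z.shape)
    return ElevationGrid(origin=(x0, y0), spacing=spacing, heights=z)


def generate_survey_network(width: float = 2000.0, height: float = 2000.0,
                            noise_sd: float = 0.0,
                            blunder: Optional[tuple] = None,
                            seed: int = 0):
    """Quadrilateral test-pit control network with a levelling loop.

    Four perimeter targets A-D counter-clockwise from the origin; six
    distance observations (four sides + two diagonals) and a closed
    four-leg levelling loop, with Gaussian noise of *noise_sd* mm and an
    optional blunder (obs_index, mm) added to one distance.  Returns
    ``(ControlNetwork, truth)`` where truth maps target -> (x, y, z).
    """
    if width <= 0 or height <= 0:
        raise InvalidArgumentError("pit dimensions must be positive")
    rng = np.random.default_rng(seed)
    truth = {
        "A": np.array([0.0, 0.0, 0.0]),
        "B": np.array([width, 0.0, -3.0]),
        "C": np.array([width, height, 2.0]),
        "D": np.array([0.0, height, 4.0]),
    }
    pairs = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C"), ("B", "D")]
    dist_obs = []
    for i, (a, b) in enumerate(pairs):
        d = float(np.linalg.norm(truth[b][:2] - truth[a][:2]))
        d += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        if blunder is not None and blunder[0] == i:
            d += blunder[1]
        dist_obs.append(DistanceObs(a, b, d))
    loop = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
    height_obs = []
    for a, b in loop:
        dz = float(truth[b][2] - truth[a][2])
        dz += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        height_obs.append(HeightObs(a, b, dz))
    network = ControlNetwork(targets=["A", "B", "C", "D"],
                             distance_obs=dist_obs, height_obs=height_obs)
    return network, truth
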