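"""Least-squares adjustment of a control-point survey network.

Plan coordinates come from trilateration: pairwise horizontal distances
among the targets, adjusted by Gauss-Newton least squares with a minimal
gauge (first target fixed at the origin, azimuth to the second target
fixed) to remove the two translational and one rotational datum
freedoms.  Heights come from levelling: observed height differences
around a closed loop whose algebraic sum — the closure error — is
distributed equally across the legs, after which the loop closes
exactly.  Residuals above a quality threshold (10 mm by default) are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from ._util import InvalidArgumentError


@dataclass
class DistanceObs:
    a: str
    b: str
    value: float          # horizontal distance, mm
    sigma: float = 1.0    # relative weight 1/sigma


@dataclass
class HeightObs:
    a: str
    b: str
    dz: float             # levelled height difference z_b - z_a, mm
    sigma: float = 1.0


@dataclass
class ControlNetwork:
    targets: list                      # names, order fixes the gauge
    distance_obs: list = field(default_factory=list)
    height_obs: list = field(default_factory=list)

    def __post_init__(self):
        names = set(self.targets)
        for o in self.distance_obs + self.height_obs:
            if o.a not in names or o.b not in names:
                raise InvalidArgumentError(f"observation references unknown target {o.a!r}/{o.b!r}")


@dataclass
class AdjustmentResult:
    adjusted_coords: dict              # name -> np.ndarray
    residuals: np.ndarray              # observed - adjusted, per observation
    redundancy: int
    closure_before: Optional[float] = None
    closure_after: Optional[float] = None
    converged: bool = True

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals))) if self.residuals.size else 0.0


def _connected(targets, obs) -> bool:
    if not targets:
        return False
    adj: dict = {t: [] for t in targets}
    for o in obs:
        adj[o.a].append(o.b)
        adj[o.b].append(o.a)
    seen = {targets[0]}
    stack = [targets[0]]
    while stack:
        for nbr in adj[stack.pop()]:
            if nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return len(seen) == len(targets)


def _trilateration_seed(network: ControlNetwork) -> dict:
    """Incremental two-circle intersection seed for Gauss-Newton."""
    obs = {frozenset((o.a, o.b)): o.value for o in network.distance_obs}

    def d(a, b):
        return obs.get(frozenset((a, b)))

    t = network.targets
    pos = {t[0]: np.zeros(2)}
    # second target on the +x axis (the gauge azimuth)
    d01 = d(t[0], t[1])
    if d01 is None:
        raise InvalidArgumentError(
            f"gauge pair {t[0]!r}-{t[1]!r} has no distance observation")
    pos[t[1]] = np.array([d01, 0.0])

    pending = [x for x in t[2:]]
    progressed = True
    while pending and progressed:
        progressed = False
        for name in list(pending):
            anchors = [(p, d(name, p)) for p in pos if d(name, p) is not None]
            if len(anchors) < 2:
                continue
            (p1, r1), (p2, r2) = anchors[:2]
            c1, c2 = pos[p1], pos[p2]
            base = np.linalg.norm(c2 - c1)
            if base == 0:
                continue
            ex = (c2 - c1) / base
            ey = np.array([-ex[1], ex[0]])
            x = (base ** 2 + r1 ** 2 - r2 ** 2) / (2 * base)
            y2 = r1 ** 2 - x ** 2
            y = np.sqrt(max(y2, 0.0))
            # keep y >= 0: the network is expected counter-clockwise; the
            # least-squares refinement is insensitive to residual error here
            pos[name] = c1 + x * ex + y * ey
            pending.remove(name)
            progressed = True
    if pending:
        raise InvalidArgumentError(
            f"cannot seed positions for targets {pending}: too few distances")
    return pos


def adjust_plan(network: ControlNetwork, max_iter: int = 100,
                tol: float = 1e-6) -> AdjustmentResult:
    """Adjust plan (x, y) coordinates from the distance observations.

    The first target is fixed at the origin and the second constrained
    to the +x axis.  With redundancy zero the exact trilateration solve
    is returned and flagged (redundancy = 0); negative redundancy is an
    error.
    """
    if len(network.targets) < 3:
        raise InvalidArgumentError("plan adjustment needs at least 3 targets")
    if not _connected(network.targets, network.distance_obs):
        raise InvalidArgumentError("distance network is not connected")
    t = network.targets
    n_unknowns = 2 * len(t) - 3  # gauge: x0, y0, y1 fixed
    redundancy = len(network.distance_obs) - n_unknowns
    if redundancy < 0:
        raise InvalidArgumentError(
            f"underdetermined network: {len(network.distance_obs)} distances "
            f"for {n_unknowns} free coordinates")

    seed = _trilateration_seed(network)

    def pack(pos):
        vec = [pos[t[1]][0]]
        for name in t[2:]:
            vec.extend(pos[name])
        return np.array(vec)

    def unpack(vec):
        pos = {t[0]: np.zeros(2), t[1]: np.array([vec[0], 0.0])}
        for i, name in enumerate(t[2:]):
            pos[name] = vec[1 + 2 * i: 3 + 2 * i]
        return pos

    weights = np.array([1.0 / o.sigma for o in network.distance_obs])

    def fun(vec):
        pos = unpack(vec)
        return weights * np.array(
            [np.linalg.norm(pos[o.b] - pos[o.a]) - o.value
             for o in network.distance_obs])

    sol = least_squares(fun, pack(seed), method="lm", max_nfev=max_iter * 10,
                        xtol=tol, ftol=1e-15, gtol=1e-15)
    pos = unpack(sol.x)
    residuals = np.array([o.value - np.linalg.norm(pos[o.b] - pos[o.a])
                          for o in network.distance_obs])
    return AdjustmentResult(adjusted_coords={k: v.copy() for k, v in pos.items()},
                            residuals=residuals, redundancy=redundancy,
                            converged=sol.success)


def adjust_heights(network: ControlNetwork, fixed: Optional[str] = None,
                   z0: float = 0.0, proportional: bool = False) -> AdjustmentResult:
    """Adjust heights from levelled differences around a loop.

    The closure error (algebraic sum of the observed differences around
    the loop) is distributed equally across the legs — or proportionally
    to leg magnitude with ``proportional=True`` — so the adjusted loop
    sums exactly to zero.  An open traverse is propagated as-is with
    closure undefined.
    """
    obs = network.height_obs
    if not obs:
        raise InvalidArgumentError("no height observations")
    if not _connected(network.targets, obs):
        raise InvalidArgumentError("levelling network is not connected")
    fixed = fixed or network.targets[0]

    degree: dict = {}
    for o in obs:
        degree[o.a] = degree.get(o.a, 0) + 1
        degree[o.b] = degree.get(o.b, 0) + 1
    is_loop = len(obs) == len([t for t in network.targets if t in degree]) \
        and all(v == 2 for v in degree.values())

    if is_loop:
        closure = float(sum(o.dz for o in obs))
        if proportional:
            total = sum(abs(o.dz) for o in obs)
            corrections = np.array([-closure * abs(o.dz) / total for o in obs]) \
                if total else np.full(len(obs), -closure / len(obs))
        else:
            corrections = np.full(len(obs), -closure / len(obs))
    else:
        closure = None
        corrections = np.zeros(len(obs))

    adjusted = [o.dz + c for o, c in zip(obs, corrections)]
    z = {fixed: z0}
    frontier = [fixed]
    while frontier:
        cur = frontier.pop()
        for o, dz_adj in zip(obs, adjusted):
            if o.a == cur and o.b not in z:
                z[o.b] = z[cur] + dz_adj
                frontier.append(o.b)
            elif o.b == cur and o.a not in z:
                z[o.a] = z[cur] - dz_adj
                frontier.append(o.a)

    residuals = -corrections  # observed - adjusted
    closure_after = float(sum(adjusted)) if is_loop else None
    coords = {name: np.array([z[name]]) for name in z}
    result = AdjustmentResult(adjusted_coords=coords, residuals=residuals,
                              redundancy=1 if is_loop else 0,
                              closure_before=closure, closure_after=closure_after)
    return result


@dataclass
class ResidualReport:
    threshold: float
    flagged: list         # (obs index, residual)
    max_abs_residual: float

    @property
    def passed(self) -> bool:
        return not self.flagged


def residual_report(result: AdjustmentResult, threshold: float = 10.0) -> ResidualReport:
    """Flag observations whose |residual| exceeds *threshold* (mm)."""
    flagged = [(i, float(r)) for i, r in enumerate(result.residuals)
               if abs(r) > threshold]
    return ResidualReport(threshold=threshold, flagged=flagged,
                          max_abs_residual=result.max_abs_residual)
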