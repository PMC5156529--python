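"""Comparative body-size/speed report across track-maker individuals.

Builds the per-individual profiles (stature, mass, speed by every
applicable method), the pairwise midpoint differences per method, and a
fixed-width rendering in the style of the printed summary table.  All
rounding happens here, in one place, half away from zero, so estimates
stay exact until display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import InvalidArgumentError, round_half_away
from .bodysize import (BodyProfile, EstimatorConstants, PointEstimate,
                       RangeEstimate, profile_individual)
from .calibration import load_all_fixtures, recover_paper_specs
from .io import summaries_from_fixtures
from .locomotion import speed_profile


@dataclass
class ComparisonReport:
    profiles: dict = field(default_factory=dict)       # individual -> BodyProfile
    speeds: dict = field(default_factory=dict)         # individual -> [SpeedEstimate]
    summaries: dict = field(default_factory=dict)      # individual -> TrackwaySummary
    stature_differences: dict = field(default_factory=dict)  # (a, b, method) -> cm
    mass_differences: dict = field(default_factory=dict)     # (a, b, method) -> kg


def _midpoint(est) -> float:
    if isinstance(est, RangeEstimate):
        return est.midpoint
    if isinstance(est, PointEstimate):
        return est.value
    raise InvalidArgumentError(f"cannot take a midpoint of {type(est).__name__}")


def pairwise_difference(profile_a: BodyProfile, profile_b: BodyProfile,
                        method: str, which: str = "stature") -> float:
    """Midpoint difference a - b for one method; mixing methods is refused."""
    attr = "stature_by_method" if which == "stature" else "mass_by_method"
    da, db = getattr(profile_a, attr), getattr(profile_b, attr)
    if method not in da or method not in db:
        raise InvalidArgumentError(
            f"method {method!r} not available for both individuals; "
            "differences across methods are not comparable")
    return _midpoint(da[method]) - _midpoint(db[method])


def build_report(summaries: dict | None = None,
                 constants: EstimatorConstants | None = None,
                 specs: dict | None = None,
                 s2_exception_ids=("S2",)) -> ComparisonReport:
    """Profile every individual and compare them pairwise.

    With no arguments the packaged printed-table fixtures are profiled,
    reproducing the published comparative table.
    """
    if summaries is None:
        summaries = summaries_from_fixtures(load_all_fixtures())
    constants = constants or EstimatorConstants()
    specs = specs or recover_paper_specs()

    report = ComparisonReport(summaries=dict(summaries))
    for ind, summary in summaries.items():
        prof = profile_individual(summary, constants, specs,
                                  s2_exception=ind in s2_exception_ids)
        report.profiles[ind] = prof
        if summary.stride_mean is not None:
            reg_stature = prof.stature_by_method.get("hs_regression")
            report.speeds[ind] = speed_profile(
                summary, prof.stature_by_method["hs_ratio"],
                spec=specs.get("speed_by_ratio"),
                regression_stature_cm=reg_stature.value if reg_stature else None)

    inds = sorted(report.profiles)
    for i, a in enumerate(inds):
        for b in inds[i + 1:]:
            for method in ("hs_ratio", "aa_ratio", "hs_regression"):
                try:
                    report.stature_differences[(a, b, method)] = pairwise_difference(
                        report.profiles[a], report.profiles[b], method, "stature")
                    report.mass_differences[(a, b, method)] = pairwise_difference(
                        report.profiles[a], report.profiles[b], method, "mass")
                except InvalidArgumentError:
                    continue
    return report


def _fmt_range(est: RangeEstimate, nd: int = 0) -> str:
    lo, hi = round_half_away(est.low, nd), round_half_away(est.high, nd)
    fmt = f"{{:.{nd}f}}"
    return f"{fmt.format(lo)}-{fmt.format(hi)}"


def render_report(report: ComparisonReport) -> str:
    """Fixed-width text rendering, one column per individual."""
    inds = sorted(report.profiles)
    width = 14
    lines = []

    def row(label, values):
        lines.append(f"{label:<38}" + "".join(f"{v:>{width}}" for v in values))

    row("Trackway", inds)
    row("Number of measurable footprints",
        [report.summaries[i].n_measurable for i in inds])
    row("Average footprint length (mm)",
        [f"{round_half_away(report.summaries[i].length_mean):g}" for i in inds])
    row("Average footprint max width (mm)",
        [(f"{round_half_away(report.summaries[i].width_mean):g}"
          + ("*" if report.summaries[i].width_overestimated else ""))
         if report.summaries[i].width_mean else "-" for i in inds])
    row("Average foot index (%)",
        [f"{round_half_away(report.summaries[i].foot_index_mean, 1):.1f}"
         if report.summaries[i].foot_index_mean else "-" for i in inds])
    row("Average step length (mm)",
        [f"{round_half_away(report.summaries[i].step_mean):g}"
         if report.summaries[i].step_mean else "-" for i in inds])
    row("Average stride length (mm)",
        [f"{round_half_away(report.summaries[i].stride_mean):g}"
         if report.summaries[i].stride_mean else "-" for i in inds])

    row("Stature, H. sapiens ratio (cm)",
        [_fmt_range(report.profiles[i].stature_by_method["hs_ratio"]) for i in inds])
    row("Stature, regression (cm)",
        [f"{round_half_away(report.profiles[i].stature_by_method['hs_regression'].value, 1):.1f}"
         if "hs_regression" in report.profiles[i].stature_by_method else "-"
         for i in inds])
    row("Stature, Au. afarensis ratio (cm)",
        [_fmt_range(report.profiles[i].stature_by_method["aa_ratio"]) for i in inds])
    row("Body mass, regression (kg)",
        [f"{round_half_away(report.profiles[i].mass_by_method['hs_regression'].value, 1):.1f}"
         if "hs_regression" in report.profiles[i].mass_by_method else "-"
         for i in inds])
    row("Body mass, Au. afarensis ratio (kg)",
        [_fmt_range(report.profiles[i].mass_by_method["aa_ratio"], 1) for i in inds])

    def speed_cells(kind):
        cells = []
        for i in inds:
            ests = report.speeds.get(i)
            if not ests:
                cells.append("-")
                continue
            alex = ests[0]
            lo, hi = getattr(alex, kind)
            cell = f"{round_half_away(lo, 2):.2f}-{round_half_away(hi, 2):.2f}"
            if len(ests) > 1 and getattr(ests[1], kind) is not None:
                cell += f" ({round_half_away(getattr(ests[1], kind), 2):.2f})"
            cells.append(cell)
        return cells

    width = 18
    row("Walking speed (m/s)", speed_cells("speed"))
    row("Relative speed (1/s)", speed_cells("relative_speed"))

    if report.stature_differences:
        lines.append("")
        lines.append("Pairwise midpoint stature differences (cm):")
        for (a, b, method), d in sorted(report.stature_differences.items()):
            lines.append(f"  {a} - {b} [{method}]: {round_half_away(d, 1):+.1f}")
    flagged = [i for i in inds if report.profiles[i].flags]
    for i in flagged:
        lines.append(f"* {i}: " + "; ".join(report.profiles[i].flags))
    return "\n".join(lines) + "\n"
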