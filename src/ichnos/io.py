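"""Delimited-text readers/writers and the ichnofauna tally.

All tabular interchange is comma-delimited UTF-8 text with a mandatory
header row; landmark sets travel as YAML (one record per footprint,
named 2-D points in mm, y increasing along the walking direction);
survey observations as (type, from, to, value_mm, sigma_mm) rows.
Malformed input is rejected with the offending line named.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from ._util import InvalidArgumentError
from .morphometry import (Footprint, FootprintMetrics, GaitSummary, Trackway,
                          TrackwaySummary, summarize_trackway)
from .survey import ControlNetwork, DistanceObs, HeightObs


class ParseError(ValueError):
    """Malformed input file (wrong schema, bad values)."""


REQUIRED_COLUMNS = ("footprint_id", "individual_id", "side", "length_mm",
                    "max_width_mm", "order_index", "gap_before")
OPTIONAL_COLUMNS = ("heel_width_mm", "foot_index_pct", "angle_of_gait_deg",
                    "width_overestimated")
_NUMERIC = ("length_mm", "max_width_mm", "heel_width_mm", "foot_index_pct",
            "angle_of_gait_deg")


def read_footprint_table(path) -> pd.DataFrame:
    """Read and validate a per-footprint measurement table.

    Returns a typed DataFrame sorted by (individual_id, order_index).
    Raises :class:`ParseError` naming the offending column/row.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot read footprint table {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no records")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS) | \
        {c for c in df.columns if c.startswith(("stature_", "mass_"))}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ParseError(f"{path}: unknown columns {unknown}")

    dup = df["footprint_id"][df["footprint_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate footprint ids {sorted(dup.unique())}")

    for i, side in enumerate(df["side"], start=2):  # +1 header, +1 one-based
        if side not in ("left", "right"):
            raise ParseError(f"{path} line {i}: side must be left/right, got {side!r}")

    for col in _NUMERIC:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (df[col].str.strip() != "") & parsed.isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ParseError(
                f"{path} line {line}: non-numeric value {df[col][bad].iloc[0]!r} in {col}")
        df[col] = parsed
    df["order_index"] = pd.to_numeric(df["order_index"], errors="raise").astype(int)
    for col in ("gap_before", "width_overestimated"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip().str.lower().isin(
                ("true", "1", "yes"))
    return df.sort_values(["individual_id", "order_index"]).reset_index(drop=True)


def write_footprint_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def footprints_from_table(df: pd.DataFrame, individual_id: str) -> Trackway:
    """Build a Trackway (metrics-only footprints) for one individual."""
    rows = df[df["individual_id"] == individual_id]
    if rows.empty:
        raise InvalidArgumentError(f"no rows for individual {individual_id!r}")
    fps = []
    for _, r in rows.iterrows():
        metrics = None
        if not pd.isna(r["length_mm"]) and not pd.isna(r["max_width_mm"]):
            metrics = FootprintMetrics(
                length=float(r["length_mm"]), max_width=float(r["max_width_mm"]),
                heel_width=None if pd.isna(r.get("heel_width_mm")) else float(r["heel_width_mm"]),
                foot_index=None if pd.isna(r.get("foot_index_pct")) else float(r["foot_index_pct"]))
        fps.append(Footprint(id=r["footprint_id"], side=r["side"], metrics=metrics,
                             gap_before=bool(r["gap_before"])))
    return Trackway(individual_id=individual_id, footprints=fps)


def gait_from_table(df: pd.DataFrame) -> GaitSummary:
    """Build a GaitSummary from a printed step/stride table."""
    steps = [(r["from_id"], r["to_id"], float(r["value_mm"]))
             for _, r in df[df["kind"] == "step"].iterrows()]
    strides = [(r["from_id"], r["to_id"], float(r["value_mm"]))
               for _, r in df[df["kind"] == "stride"].iterrows()]
    by_side = {}
    for s in ("right", "left"):
        vals = [float(r["value_mm"]) for _, r in df.iterrows()
                if r["kind"] == "stride" and r["from_side"] == s]
        if vals:
            by_side[s] = float(np.mean(vals))
    return GaitSummary(
        step_lengths=steps, stride_lengths=strides, angles_of_gait=[],
        mean_step=float(np.mean([v for *_, v in steps])) if steps else None,
        mean_stride=float(np.mean([v for *_, v in strides])) if strides else None,
        mean_stride_by_side=by_side)


def summaries_from_fixtures(fixtures: dict) -> dict:
    """Per-individual TrackwaySummary set from the packaged printed tables.

    S1 and S2 are aggregated from their per-print rows (and the S1 gait
    table); the Site G columns, for which no per-print data were ever
    published, come directly from the summary table.
    """
    fp = fixtures["table2_footprints"]
    gait = gait_from_table(fixtures["table2_gait"])
    t3 = fixtures["table3"]
    out = {}
    for ind in fp["individual_id"].unique():
        rows = fp[fp["individual_id"] == ind]
        metrics = [FootprintMetrics(length=float(r["length_mm"]),
                                    max_width=float(r["max_width_mm"]),
                                    foot_index=float(r["foot_index_pct"]))
                   for _, r in rows.iterrows() if not pd.isna(r["length_mm"])]
        over = bool(rows["width_overestimated"].any())
        out[ind] = summarize_trackway(ind, metrics, gait if ind == "S1" else None,
                                      width_overestimated=over)
    for _, r in t3.iterrows():
        ind = r["individual"]
        if ind in out:
            continue
        s = TrackwaySummary(individual_id=ind, n_measurable=int(r["n_measurable"]),
                            width_overestimated=bool(r["width_overestimated"]))
        s.length_mean = float(r["length_mm"])
        s.width_mean = float(r["max_width_mm"])
        s.foot_index_mean = float(r["foot_index_pct"])
        s.step_mean = None if pd.isna(r["step_mm"]) else float(r["step_mm"])
        s.stride_mean = None if pd.isna(r["stride_mm"]) else float(r["stride_mm"])
        out[ind] = s
    return out


def read_landmark_file(path) -> list:
    """Read a YAML landmark file into Footprint objects."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not doc or "footprints" not in doc:
        raise ParseError(f"{path}: no 'footprints' records")
    fps = []
    for rec in doc["footprints"]:
        try:
            lm = {k: np.asarray(v, dtype=float) for k, v in (rec.get("landmarks") or {}).items()}
            fps.append(Footprint(id=str(rec["id"]), side=rec["side"],
                                 landmarks=lm or None,
                                 gap_before=bool(rec.get("gap_before", False))))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed record {rec!r}: {exc}") from exc
    return fps


def write_landmark_file(footprints, path) -> None:
    doc = {"units": "mm", "footprints": []}
    for fp in footprints:
        rec = {"id": fp.id, "side": fp.side, "gap_before": fp.gap_before}
        if fp.landmarks:
            rec["landmarks"] = {k: [float(v[0]), float(v[1])]
                                for k, v in fp.landmarks.items()}
        doc["footprints"].append(rec)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def tally_ichnofauna(df: pd.DataFrame) -> dict:
    """Row/column/grand totals of a taxon x location count table.

    A printed 'Total' row, if present, is cross-checked against the
    computed sums; a mismatch raises.
    """
    body = df[df["taxon"] != "Total"].copy()
    loc_cols = [c for c in df.columns if c not in ("taxon", "total")]
    for col in loc_cols:
        vals = pd.to_numeric(body[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise InvalidArgumentError(
                f"ichnofauna column {col!r} must hold non-negative integers")
        body[col] = vals.astype(int)
    by_taxon = {r["taxon"]: int(sum(r[c] for c in loc_cols)) for _, r in body.iterrows()}
    by_location = {c: int(body[c].sum()) for c in loc_cols}
    grand = int(sum(by_location.values()))
    printed = df[df["taxon"] == "Total"]
    if not printed.empty:
        row = printed.iloc[0]
        for c in loc_cols:
            if int(row[c]) != by_location[c]:
                raise InvalidArgumentError(
                    f"printed total for {c!r} ({int(row[c])}) != computed {by_location[c]}")
        if "total" in df.columns and int(row["total"]) != grand:
            raise InvalidArgumentError(
                f"printed grand total {int(row['total'])} != computed {grand}")
    return {"by_taxon": by_taxon, "by_location": by_location, "grand_total": grand}


def read_survey_obs(path) -> ControlNetwork:
    """Read (type, from, to, value_mm[, sigma_mm]) survey observations."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot read survey file {path}: {exc}") from exc
    for col in ("type", "from", "to", "value_mm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    dist, hgt, targets = [], [], []
    for i, r in df.iterrows():
        sigma = float(r["sigma_mm"]) if "sigma_mm" in df.columns and not pd.isna(r.get("sigma_mm")) else 1.0
        for t in (r["from"], r["to"]):
            if t not in targets:
                targets.append(t)
        if r["type"] == "distance":
            dist.append(DistanceObs(r["from"], r["to"], float(r["value_mm"]), sigma))
        elif r["type"] == "height_diff":
            hgt.append(HeightObs(r["from"], r["to"], float(r["value_mm"]), sigma))
        else:
            raise ParseError(f"{path} line {i + 2}: unknown observation type {r['type']!r}")
    return ControlNetwork(targets=targets, distance_obs=dist, height_obs=hgt)
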