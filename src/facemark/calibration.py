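"""Manual-placement analytics.

Inverts clicked marker coordinates back to (angle, distance-ratio)
readings, aggregates them into a per-subject calibration table with
Average and Std Dev rows, and compares a manual calibration against an
automated placement profile.

The package ships the reference manual-placement readings — 10 subjects,
each the mean of 3 click trials per marker — that define the default
automated placement profile.  ``load_reference_calibration`` returns
that table; aggregating it reproduces the profile in
:func:`facemark.geometry.default_profile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import (
    MARKER_IDS,
    FaceGeometry,
    MarkerPlacement,
    PlacementProfile,
    ellipse_radius_at,
    marker_distance,
)

#: Marker roles: mouth-corner angles are reported as the sweep from the
#: +x axis through the lower hemisphere (i.e. 180 - elevation), all
#: other markers as the plain elevation from the horizontal.
MOUTH_CORNER_IDS = ("p_m1", "p_m2")
MIDLINE_IDS = ("p_m3", "p_m4")

_ROLE_FLAGS = {
    "p_e1": ("upper", "left"), "p_e2": ("upper", "right"),
    "p_e3": ("upper", "left"), "p_e4": ("upper", "right"),
    "p_m1": ("lower", "left"), "p_m2": ("lower", "right"),
    "p_m3": ("lower", "midline"), "p_m4": ("lower", "midline"),
}


class CalibrationError(ValueError):
    pass


@dataclass
class ClickLog:
    """One manual placement trial: eight clicked marker positions on a
    face image with known geometry."""

    subject_id: str
    trial_id: str
    clicks: dict[str, tuple[float, float]]
    geometry: FaceGeometry

    def __post_init__(self) -> None:
        missing = set(MARKER_IDS) - set(self.clicks)
        if missing:
            raise CalibrationError(
                f"subject {self.subject_id} trial {self.trial_id}: "
                f"missing clicks for {sorted(missing)}"
            )


@dataclass
class CalibrationTable:
    """Per-subject (angle, ratio) means plus Average / Std Dev rows.

    ``per_subject`` is a DataFrame indexed by subject with a two-level
    column index (marker_id, quantity) where quantity is ``angle_deg``
    or ``distance_ratio``.  ``average`` and ``std_dev`` are Series over
    the same columns; the standard deviation uses the n-1 denominator.
    """

    per_subject: pd.DataFrame
    average: pd.Series
    std_dev: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.per_subject.copy()
        out.loc["Average"] = self.average
        out.loc["Std Dev"] = self.std_dev
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def angle_ratio_from_point(
    geom: FaceGeometry,
    point: tuple[float, float],
    marker_role: str | None = None,
) -> tuple[float, float]:
    """Invert a marker position to its (angle, distance-ratio) reading.

    The angle is the unsigned elevation of the point from the horizontal
    through the face centre; for mouth-corner roles it is reported as
    ``180 - elevation`` so that the conventional ~130 deg reading is
    recovered.  The ratio is the Euclidean distance from the centre
    divided by the ellipse radius along the point's direction.
    """
    dx = point[0] - geom.center[0]
    dy = point[1] - geom.center[1]
    d = math.hypot(dx, dy)
    if d == 0:
        raise CalibrationError("point coincides with the face centre: angle undefined")
    elevation = math.degrees(math.atan2(abs(dy), abs(dx)))
    ratio = d / ellipse_radius_at(geom, elevation)
    if marker_role in MOUTH_CORNER_IDS:
        return (180.0 - elevation, ratio)
    return (elevation, ratio)


def _summarize(per_subject: pd.DataFrame) -> CalibrationTable:
    return CalibrationTable(
        per_subject=per_subject,
        average=per_subject.mean(axis=0),
        std_dev=per_subject.std(axis=0, ddof=1),
    )


def aggregate_calibration(logs: list[ClickLog]) -> CalibrationTable:
    """Aggregate click trials into a calibration table.

    Each subject's reading per marker is the mean over that subject's
    trials; the Average and Std Dev rows are then taken over subjects.
    """
    if not logs:
        raise CalibrationError("no click logs supplied")
    records = []
    for log in logs:
        for mid in MARKER_IDS:
            angle, ratio = angle_ratio_from_point(
                log.geometry, log.clicks[mid], marker_role=mid
            )
            records.append(
                {"subject": log.subject_id, "trial": log.trial_id,
                 "marker_id": mid, "angle_deg": angle, "distance_ratio": ratio}
            )
    df = pd.DataFrame.from_records(records)
    per_subject = (
        df.groupby(["subject", "marker_id"])[["angle_deg", "distance_ratio"]]
        .mean()
        .unstack("marker_id")
        .swaplevel(axis=1)
        .sort_index(axis=1)
    )
    return _summarize(per_subject)


def load_reference_calibration() -> pd.DataFrame:
    """The packaged reference manual-placement readings.

    Long-form DataFrame with columns subject, marker_id, angle_deg,
    distance_ratio; one row per subject x marker (mean of 3 trials).
    """
    with resources.files("facemark.data").joinpath(
        "manual_placement_table.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def summarize_readings(readings: pd.DataFrame) -> CalibrationTable:
    """Build a :class:`CalibrationTable` from long-form per-subject
    readings (as returned by :func:`load_reference_calibration`)."""
    per_subject = (
        readings.set_index(["subject", "marker_id"])[
            ["angle_deg", "distance_ratio"]
        ]
        .unstack("marker_id")
        .swaplevel(axis=1)
        .sort_index(axis=1)
    )
    return _summarize(per_subject)


def profile_from_calibration(table: CalibrationTable) -> PlacementProfile:
    """Turn a calibration table's Average row into a placement profile."""
    placements = {}
    for mid in MARKER_IDS:
        hemisphere, side = _ROLE_FLAGS[mid]
        placements[mid] = MarkerPlacement(
            angle_deg=float(table.average[(mid, "angle_deg")]),
            ratio=float(table.average[(mid, "distance_ratio")]),
            hemisphere=hemisphere,
            side=side,
        )
    return PlacementProfile(placements)


def placement_error(
    manual: CalibrationTable, auto: PlacementProfile
) -> pd.DataFrame:
    """Absolute angle and ratio differences between a manual calibration
    Average row and an automated placement profile, per marker."""
    rows = []
    for mid in MARKER_IDS:
        rows.append(
            {
                "marker_id": mid,
                "angle_error_deg": abs(
                    float(manual.average[(mid, "angle_deg")]) - auto[mid].angle_deg
                ),
                "ratio_error": abs(
                    float(manual.average[(mid, "distance_ratio")]) - auto[mid].ratio
                ),
            }
        )
    return pd.DataFrame(rows).set_index("marker_id")


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places (table
    convention for comparing against printed values)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{x:.{decimals + 6}f}").quantize(q, rounding=ROUND_HALF_UP))


def clicks_from_profile(
    geom: FaceGeometry, profile: PlacementProfile, jitter: np.ndarray | None = None
) -> dict[str, tuple[float, float]]:
    """Forward-generate click positions from a profile (test/demo aid).

    ``jitter`` is an optional (8, 2) array of pixel offsets added to the
    ideal positions, emulating imprecise clicking.
    """
    from .geometry import place_markers

    ms = place_markers(geom, profile)
    clicks = {}
    for i, mid in enumerate(MARKER_IDS):
        x, y = ms.markers[mid]
        if jitter is not None:
            x, y = x + jitter[i, 0], y + jitter[i, 1]
        clicks[mid] = (x, y)
    return clicks
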