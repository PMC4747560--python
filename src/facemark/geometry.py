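"""Geometric face model and automated virtual-marker placement.

The face is modelled as an ellipse centred on a reference point derived
from the eye positions: the centre sits on the vertical through the
midpoint of the eyes, half the eye-to-mouth distance below the eye line.
Eight virtual markers (four on the eyebrows, four around the mouth) are
placed from that centre at calibrated polar angles and distance ratios,
where the ratio is measured against the ellipse radius along the
marker's direction.

Image coordinates are used throughout: origin top-left, x to the right,
y downward, continuous (sub-pixel) values.  Angles are the unsigned
sweep from the +x axis through the marker's hemisphere, so an eyebrow
marker at 45 deg points up-and-out while a mouth-corner marker at
130 deg points down-and-out.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import yaml

#: Canonical marker identifiers, eyebrows first, then mouth.
MARKER_IDS: tuple[str, ...] = (
    "p_e1", "p_e2", "p_e3", "p_e4", "p_m1", "p_m2", "p_m3", "p_m4",
)

#: Default angle (deg) and distance ratio per marker, from the manual
#: calibration study (mean over 10 subjects, 3 trials each), together
#: with hemisphere and side flags.
_DEFAULT_PLACEMENTS: dict[str, tuple[float, float, str, str]] = {
    "p_e1": (45.08, 0.7232, "upper", "left"),
    "p_e2": (45.17, 0.5521, "upper", "right"),
    "p_e3": (65.10, 0.7191, "upper", "left"),
    "p_e4": (65.18, 0.5570, "upper", "right"),
    "p_m1": (130.25, 0.7296, "lower", "left"),
    "p_m2": (129.97, 0.7337, "lower", "right"),
    "p_m3": (90.19, 0.3350, "lower", "midline"),
    "p_m4": (89.99, 0.3234, "lower", "midline"),
}


class GeometryError(ValueError):
    """Raised for degenerate face geometry (zero eye distance etc.)."""


@dataclass(frozen=True)
class EyePair:
    """Left and right eye centres in image coordinates.

    ``left_eye`` is the eye with the smaller x coordinate (image left).
    """

    left_eye: tuple[float, float]
    right_eye: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.left_eye[0] < self.right_eye[0]:
            raise GeometryError(
                "left eye must lie left of the right eye in image coordinates"
            )
        if self.interocular <= 0:
            raise GeometryError("inter-eye distance must be positive")

    @property
    def interocular(self) -> float:
        """Euclidean distance between the eye centres, in pixels."""
        return math.hypot(
            self.right_eye[0] - self.left_eye[0],
            self.right_eye[1] - self.left_eye[1],
        )

    def mirrored(self, axis_x: float) -> "EyePair":
        """Reflect the pair about the vertical line ``x = axis_x``."""
        lx, ly = self.left_eye
        rx, ry = self.right_eye
        return EyePair((2 * axis_x - rx, ry), (2 * axis_x - lx, ly))


@dataclass(frozen=True)
class FaceGeometry:
    """Face centre and ellipse semi-axes, all in pixels."""

    center: tuple[float, float]
    semi_axis_x: float
    semi_axis_y: float

    def __post_init__(self) -> None:
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise GeometryError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class MarkerPlacement:
    """Polar placement of one marker relative to the face centre."""

    angle_deg: float
    ratio: float
    hemisphere: str  # "upper" | "lower"
    side: str        # "left" | "right" | "midline"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.5:
            raise GeometryError(f"distance ratio {self.ratio} outside [0, 1.5]")
        if self.hemisphere not in ("upper", "lower"):
            raise GeometryError(f"unknown hemisphere {self.hemisphere!r}")
        if self.side not in ("left", "right", "midline"):
            raise GeometryError(f"unknown side {self.side!r}")


@dataclass(frozen=True)
class PlacementProfile:
    """Per-marker (angle, ratio, hemisphere, side) placement table."""

    placements: Mapping[str, MarkerPlacement]

    def __post_init__(self) -> None:
        missing = set(MARKER_IDS) - set(self.placements)
        if missing:
            raise GeometryError(f"profile missing markers: {sorted(missing)}")

    def __getitem__(self, marker_id: str) -> MarkerPlacement:
        return self.placements[marker_id]

    def to_dict(self) -> dict:
        return {
            mid: {
                "angle_deg": p.angle_deg,
                "ratio": p.ratio,
                "hemisphere": p.hemisphere,
                "side": p.side,
            }
            for mid, p in self.placements.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping]) -> "PlacementProfile":
        return cls(
            {
                mid: MarkerPlacement(
                    float(v["angle_deg"]), float(v["ratio"]),
                    str(v["hemisphere"]), str(v["side"]),
                )
                for mid, v in d.items()
            }
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PlacementProfile":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_profile() -> PlacementProfile:
    """The calibrated default placement profile.

    Angles and ratios are the per-marker means of the manual placement
    study shipped with :mod:`facemark.calibration`; eyebrow markers sit
    in the upper hemisphere at ~45 and ~65 deg, mouth corners at
    ~130 deg in the lower hemisphere, and the upper/lower mouth markers
    on the vertical axis below the centre.
    """
    return PlacementProfile(
        {mid: MarkerPlacement(*vals) for mid, vals in _DEFAULT_PLACEMENTS.items()}
    )


@dataclass
class MarkerSet:
    """The eight placed markers plus the face centre for one frame."""

    frame_index: int
    markers: dict[str, tuple[float, float]]
    center: tuple[float, float]

    def __post_init__(self) -> None:
        missing = set(MARKER_IDS) - set(self.markers)
        if missing:
            raise GeometryError(f"marker set missing: {sorted(missing)}")
        for mid, (x, y) in self.markers.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise GeometryError(f"non-finite coordinate for {mid}")


def compute_center(eyes: EyePair, eye_mouth_distance: float) -> tuple[float, float]:
    """Face centre from the eyes: midpoint x, eye line plus half the
    eye-to-mouth distance in y.

    Parameters
    ----------
    eyes:
        Detected or manually supplied eye centres.
    eye_mouth_distance:
        Vertical distance from the eye line to the mouth, in pixels.
    """
    if eye_mouth_distance <= 0:
        raise GeometryError("eye-to-mouth distance must be positive")
    x = 0.5 * (eyes.left_eye[0] + eyes.right_eye[0])
    y = 0.5 * (eyes.left_eye[1] + eyes.right_eye[1]) + 0.5 * eye_mouth_distance
    return (x, y)


def geometry_from_eyes(
    eyes: EyePair,
    eye_mouth_distance: float | None = None,
    *,
    eye_mouth_factor: float = 1.1,
    box_width_factor: float = 2.5,
    box_aspect: float = 1.3,
    axis_scale: float = 1.0,
) -> FaceGeometry:
    """Construct a :class:`FaceGeometry` from eye centres alone.

    When no mouth detection is available the eye-to-mouth distance
    defaults to ``eye_mouth_factor`` times the inter-eye distance.  The
    ellipse semi-axes derive from an inferred face box of width
    ``box_width_factor`` times the inter-eye distance and height
    ``box_aspect`` times the width.
    """
    d = eyes.interocular
    if eye_mouth_distance is None:
        eye_mouth_distance = eye_mouth_factor * d
    center = compute_center(eyes, eye_mouth_distance)
    width = box_width_factor * d
    return FaceGeometry(center, width / 2.0, (width * box_aspect) / 2.0 * axis_scale)


def geometry_from_box(
    face_box: tuple[float, float, float, float],
    center: tuple[float, float],
    axis_scale: float = 1.0,
) -> FaceGeometry:
    """Ellipse semi-axes from a detection bounding box ``(x, y, w, h)``."""
    _, _, w, h = face_box
    if w <= 0 or h <= 0:
        raise GeometryError("face box must have positive extent")
    return FaceGeometry(center, w / 2.0, h / 2.0 * axis_scale)


def ellipse_radius_at(geom: FaceGeometry, angle_deg: float) -> float:
    """Centre-polar radius of the face ellipse at ``angle_deg``.

    r(theta) = a*b / sqrt((b cos theta)^2 + (a sin theta)^2); r(0) = a
    and r(90) = b.  The radius only depends on the axis of the
    direction, so the hemisphere/side conventions do not matter here.
    """
    a, b = geom.semi_axis_x, geom.semi_axis_y
    th = math.radians(angle_deg)
    return a * b / math.hypot(b * math.cos(th), a * math.sin(th))


def _direction(p: MarkerPlacement) -> tuple[float, float]:
    """Unit direction for a placement in image coordinates (y down)."""
    if p.side == "midline":
        return (0.0, 1.0 if p.hemisphere == "lower" else -1.0)
    th = math.radians(p.angle_deg)
    ex = abs(math.cos(th)) * (-1.0 if p.side == "left" else 1.0)
    ey = abs(math.sin(th)) * (1.0 if p.hemisphere == "lower" else -1.0)
    return (ex, ey)


def place_marker(geom: FaceGeometry, p: MarkerPlacement) -> tuple[float, float]:
    """Position of a single marker for the given geometry.

    Midline markers are pinned to the vertical axis through the centre:
    their distance is ``ratio * semi_axis_y`` regardless of the small
    deviation of the calibrated angle from 90 deg.
    """
    ex, ey = _direction(p)
    if p.side == "midline":
        r = geom.semi_axis_y
    else:
        r = ellipse_radius_at(geom, p.angle_deg)
    d = p.ratio * r
    return (geom.center[0] + d * ex, geom.center[1] + d * ey)


def place_markers(
    geom: FaceGeometry,
    profile: PlacementProfile | None = None,
    *,
    frame_index: int = 0,
    image_shape: tuple[int, int] | None = None,
    clamp: bool = False,
) -> MarkerSet:
    """Place all eight virtual markers for one face.

    If ``image_shape`` (height, width) is given, markers falling outside
    the image trigger a warning and, with ``clamp=True``, are clamped to
    the image bounds.
    """
    profile = profile or default_profile()
    markers: dict[str, tuple[float, float]] = {}
    for mid in MARKER_IDS:
        x, y = place_marker(geom, profile[mid])
        if image_shape is not None:
            h, w = image_shape
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                warnings.warn(
                    f"marker {mid} at ({x:.1f}, {y:.1f}) outside image "
                    f"{w}x{h}", stacklevel=2,
                )
                if clamp:
                    x = min(max(x, 0.0), float(w - 1))
                    y = min(max(y, 0.0), float(h - 1))
        markers[mid] = (x, y)
    return MarkerSet(frame_index=frame_index, markers=markers, center=geom.center)


def marker_distance(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Euclidean distance between two points (Pythagorean theorem)."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def write_marker_sets(path, marker_sets: Iterable[MarkerSet]) -> None:
    """Write marker sets as CSV ``frame,marker_id,x,y`` (6 decimals)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "marker_id", "x", "y"])
        for ms in marker_sets:
            writer.writerow([ms.frame_index, "center",
                             f"{ms.center[0]:.6f}", f"{ms.center[1]:.6f}"])
            for mid in MARKER_IDS:
                x, y = ms.markers[mid]
                writer.writerow([ms.frame_index, mid, f"{x:.6f}", f"{y:.6f}"])


def read_marker_sets(path) -> list[MarkerSet]:
    """Read marker sets written by :func:`write_marker_sets`."""
    frames: dict[int, dict[str, tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            fi = int(row["frame"])
            frames.setdefault(fi, {})[row["marker_id"]] = (
                float(row["x"]), float(row["y"]),
            )
    out = []
    for fi in sorted(frames):
        d = frames[fi]
        center = d.pop("center")
        out.append(MarkerSet(frame_index=fi, markers=d, center=center))
    return out


def mirror_markers(ms: MarkerSet, axis_x: float) -> MarkerSet:
    """Reflect a marker set about the vertical line ``x = axis_x``,
    swapping left/right marker identities."""
    swap = {"p_e1": "p_e2", "p_e2": "p_e1", "p_e3": "p_e4", "p_e4": "p_e3",
            "p_m1": "p_m2", "p_m2": "p_m1", "p_m3": "p_m3", "p_m4": "p_m4"}
    markers = {
        swap[mid]: (2 * axis_x - x, y) for mid, (x, y) in ms.markers.items()
    }
    cx, cy = ms.center
    return MarkerSet(ms.frame_index, markers, (2 * axis_x - cx, cy))
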