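"""Frame-sequence input and face/eye localization.

Detection is a pluggable backend behind :func:`detect_face`; the
pipeline never depends on a particular detector.  Two backends ship
with the package:

* :class:`ManualEyeProvider` — the caller supplies eye centres (from a
  click, a file, or generator ground truth) and the face box is
  inferred from the inter-eye distance.
* :class:`BrightRegionDetector` — a segmentation detector for frontal
  faces rendered by :mod:`facemark.synthface` (bright elliptical face
  on a darker background, dark eye blobs), built on connected-component
  labelling.

Any object with a ``detect(frame) -> list[FaceDetection]`` method can
serve as a backend, e.g. an adapter around an external cascade
classifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .geometry import EyePair

#: Rec. 601 luma weights used for colour-to-grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class AcquisitionError(ValueError):
    """Raised for unreadable or inconsistent input sequences."""


class DetectionError(RuntimeError):
    """Raised when no face can be located in a frame."""


@dataclass
class FrameSequence:
    """An ordered grayscale frame stack.

    ``frames`` is a (n, height, width) float array with values in
    0–255; ``frame_rate`` is metadata only.
    """

    frames: np.ndarray
    frame_rate: float = 30.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise AcquisitionError("a sequence needs >= 1 frame of equal size")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class FaceDetection:
    """One localized face: bounding box plus eye centres."""

    face_box: tuple[float, float, float, float]  # x, y, w, h
    eyes: EyePair
    detector_name: str = ""

    def __post_init__(self) -> None:
        x, y, w, h = self.face_box
        if w <= 0 or h <= 0:
            raise AcquisitionError("face box must have positive extent")
        for ex, ey in (self.eyes.left_eye, self.eyes.right_eye):
            if not (x <= ex <= x + w and y <= ey <= y + h):
                raise AcquisitionError("eyes must lie inside the face box")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance conversion; grayscale input passes through unchanged."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3] @ _LUMA
    raise AcquisitionError(f"unsupported image shape {image.shape}")


def _numeric_key(path: Path) -> tuple:
    m = re.search(r"(\d+)(?=\D*$)", path.stem)
    return (0, int(m.group(1)), path.name) if m else (1, 0, path.name)


def load_sequence(path, frame_rate: float = 30.0) -> FrameSequence:
    """Load a directory of PNG/JPEG frames ordered by numeric suffix.

    Colour frames are converted to grayscale by luminance.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise AcquisitionError(f"not a directory: {directory}")
    files = sorted(
        (p for p in directory.iterdir()
         if p.suffix.lower() in (".png", ".jpg", ".jpeg")),
        key=_numeric_key,
    )
    if not files:
        raise AcquisitionError(f"no image frames found in {directory}")
    frames = []
    for f in files:
        try:
            frames.append(to_grayscale(iio.imread(f)))
        except (OSError, ValueError) as exc:
            raise AcquisitionError(f"unreadable frame {f.name}: {exc}") from exc
    shapes = {fr.shape for fr in frames}
    if len(shapes) > 1:
        raise AcquisitionError(f"inconsistent frame dimensions: {sorted(shapes)}")
    return FrameSequence(np.stack(frames), frame_rate=frame_rate,
                         source_id=str(directory))


class DetectorBackend(Protocol):
    def detect(self, frame: np.ndarray) -> list[FaceDetection]: ...


@dataclass
class ManualEyeProvider:
    """Backend that trusts caller-supplied eye centres.

    The face box is inferred from the inter-eye distance: width
    ``box_width_factor`` times the distance, height ``box_aspect``
    times the width, eyes sitting ``eye_level`` of the way down the
    box.
    """

    eyes: EyePair
    box_width_factor: float = 2.5
    box_aspect: float = 1.3
    eye_level: float = 0.4

    def detect(self, frame: np.ndarray) -> list[FaceDetection]:
        d = self.eyes.interocular
        w = self.box_width_factor * d
        h = self.box_aspect * w
        cx = 0.5 * (self.eyes.left_eye[0] + self.eyes.right_eye[0])
        ey = 0.5 * (self.eyes.left_eye[1] + self.eyes.right_eye[1])
        box = (cx - w / 2.0, ey - self.eye_level * h, w, h)
        return [FaceDetection(box, self.eyes, detector_name="manual")]


@dataclass
class BrightRegionDetector:
    """Segmentation detector for synthetic frontal faces.

    Segments the face as the largest connected region brighter than
    ``face_threshold`` and the eyes as the two largest dark blobs
    (below ``eye_threshold``) in the upper half of the face box.
    """

    face_threshold: float = 120.0
    eye_threshold: float = 90.0
    min_eye_area: int = 4

    def detect(self, frame: np.ndarray) -> list[FaceDetection]:
        frame = np.asarray(frame, dtype=np.float64)
        mask = frame > self.face_threshold
        labels, n = ndimage.label(mask)
        if n == 0:
            return []
        detections = []
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        lab = int(np.argmax(areas)) + 1
        region = ndimage.binary_fill_holes(labels == lab)
        ys, xs = np.nonzero(region)
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
        box = (float(x0), float(y0), float(x1 - x0 + 1), float(y1 - y0 + 1))
        # eyes: dark blobs in the upper half of the (hole-filled) face
        upper = region.copy()
        upper[(y0 + y1) // 2:, :] = False
        dark = (frame < self.eye_threshold) & upper
        elab, en = ndimage.label(dark)
        if en < 2:
            return []
        eareas = ndimage.sum_labels(dark, elab, index=np.arange(1, en + 1))
        order = np.argsort(eareas)[::-1]
        if eareas[order[1]] < self.min_eye_area:
            return []
        centers = ndimage.center_of_mass(dark, elab, [order[0] + 1, order[1] + 1])
        pts = sorted(((cx, cy) for cy, cx in centers), key=lambda p: p[0])
        try:
            eyes = EyePair(tuple(pts[0]), tuple(pts[1]))
            detections.append(
                FaceDetection(box, eyes, detector_name="bright-region")
            )
        except ValueError:
            return []
        return detections


def detect_face(frame: np.ndarray, backend: DetectorBackend) -> FaceDetection:
    """Run a detector backend and return the largest detected face.

    Ties on area break toward the leftmost-topmost box.  Raises
    :class:`DetectionError` when nothing is found so that callers can
    fall back to the previous frame's geometry.
    """
    detections = backend.detect(np.asarray(frame))
    if not detections:
        raise DetectionError("no face found in frame")
    return max(
        detections,
        key=lambda d: (d.face_box[2] * d.face_box[3],
                       -d.face_box[0], -d.face_box[1]),
    )
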