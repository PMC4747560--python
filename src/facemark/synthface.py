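"""Synthetic face-sequence generator with known marker ground truth.

Renders a parametric frontal face — bright elliptical face on a darker
background, two dark eye blobs, eyebrow strokes, an elliptical mouth
outline, and a dot at each virtual-marker position — and deforms it
per emotion with a ramp-and-hold temporal profile.  The brow strokes
and mouth outline are redrawn each frame from the current marker
positions, so all local image structure moves coherently with the
ground truth and the markers themselves are visible high-contrast
features (the rendered analogue of sticker markers).

Emotion deformation templates are authored from standard FACS action
descriptions (brow raiser, lip-corner puller, and so on); they are
conventions of this generator, with per-marker apex displacements
expressed in units of the inter-eye distance.

A landmark-only path (:func:`simulate_trials`) skips rendering and
tracking entirely and produces labelled feature trials for classifier
experiments at the scale of the emulated study: 30 subjects, two
trials per emotion, six emotions, 6-second expressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .acquisition import FrameSequence
from .classify import LabeledTrialSet
from .features import cmd_series, md_series, trial_statistics
from .geometry import (
    MARKER_IDS,
    EyePair,
    FaceGeometry,
    MarkerSet,
    default_profile,
    geometry_from_eyes,
    place_markers,
)
from .lktrack import CENTER_ID, TrackState


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class FaceSpec:
    """Parameters of the rendered synthetic face.

    The default face emulates a webcam close-up: a 160-px-wide frame
    with a 48-px inter-eye distance.  ``noise_sigma`` is the standard
    deviation of per-frame additive Gaussian intensity noise (0–255
    scale); ``texture_amp`` the amplitude of the static smooth facial
    texture that keeps the tracker well-conditioned.
    """

    image_size: tuple[int, int] = (176, 160)  # (height, width)
    left_eye: tuple[float, float] = (56.0, 60.0)
    right_eye: tuple[float, float] = (104.0, 60.0)
    noise_sigma: float = 2.0
    texture_amp: float = 5.0
    texture_seed: int = 7
    background: float = 60.0
    face_albedo: float = 190.0

    @property
    def eyes(self) -> EyePair:
        return EyePair(self.left_eye, self.right_eye)

    @property
    def interocular(self) -> float:
        return self.eyes.interocular

    def geometry(self) -> FaceGeometry:
        return geometry_from_eyes(self.eyes)

    def base_markers(self) -> MarkerSet:
        return place_markers(self.geometry())


@dataclass(frozen=True)
class EmotionField:
    """Per-marker apex displacements for one emotion.

    Displacements are (dx, dy) in units of the inter-eye distance;
    image convention (y down), so a brow raise has negative dy.
    ``ramp_fraction`` of the frames ramp linearly from neutral to the
    apex, the rest hold.
    """

    label: str
    displacements: Mapping[str, tuple[float, float]]
    ramp_fraction: float = 0.5

    def __post_init__(self) -> None:
        for mid, (dx, dy) in self.displacements.items():
            if mid not in MARKER_IDS:
                raise GenerationError(f"unknown marker {mid} in template")
            if math.hypot(dx, dy) > 0.5:
                raise GenerationError(
                    f"template displacement for {mid} exceeds half the "
                    "inter-eye distance"
                )

    def apex(self, mid: str) -> tuple[float, float]:
        return tuple(self.displacements.get(mid, (0.0, 0.0)))

    def profile(self, n_frames: int) -> np.ndarray:
        """Ramp-and-hold activation per frame; frame 0 is neutral."""
        ramp = max(1, int(round(self.ramp_fraction * (n_frames - 1))))
        t = np.arange(n_frames, dtype=np.float64)
        return np.clip(t / ramp, 0.0, 1.0)


def default_emotion_fields() -> dict[str, EmotionField]:
    """The six authored emotion templates.

    surprise: brows raised, jaw drops; happiness: lip corners pulled
    out and up; anger: brows lowered and drawn together, lips pressed;
    sadness: lip corners down, inner brows raised; fear: brows raised,
    mouth stretched and slightly open; disgust: upper lip raised,
    brows slightly lowered.
    """
    t = {
        "surprise": {
            "p_e1": (0.0, -0.12), "p_e2": (0.0, -0.12),
            "p_e3": (0.0, -0.12), "p_e4": (0.0, -0.12),
            "p_m1": (0.03, 0.02), "p_m2": (-0.03, 0.02),
            "p_m3": (0.0, -0.01), "p_m4": (0.0, 0.12),
        },
        "happiness": {
            "p_e1": (0.0, -0.01), "p_e2": (0.0, -0.01),
            "p_m1": (-0.08, -0.06), "p_m2": (0.08, -0.06),
            "p_m3": (0.0, -0.01), "p_m4": (0.0, -0.02),
        },
        "anger": {
            "p_e1": (0.04, 0.05), "p_e2": (-0.04, 0.05),
            "p_e3": (0.05, 0.06), "p_e4": (-0.05, 0.06),
            "p_m1": (0.0, 0.02), "p_m2": (0.0, 0.02),
            "p_m3": (0.0, 0.02), "p_m4": (0.0, -0.02),
        },
        "sadness": {
            "p_e3": (0.0, -0.05), "p_e4": (0.0, -0.05),
            "p_m1": (-0.01, 0.07), "p_m2": (0.01, 0.07),
            "p_m4": (0.0, 0.02),
        },
        "fear": {
            "p_e1": (0.0, -0.08), "p_e2": (0.0, -0.08),
            "p_e3": (0.0, -0.08), "p_e4": (0.0, -0.08),
            "p_m1": (-0.06, 0.0), "p_m2": (0.06, 0.0),
            "p_m4": (0.0, 0.06),
        },
        "disgust": {
            "p_e3": (0.0, 0.03), "p_e4": (0.0, 0.03),
            "p_m1": (0.0, 0.03), "p_m2": (0.0, 0.03),
            "p_m3": (0.0, -0.06),
        },
    }
    return {label: EmotionField(label, disp) for label, disp in t.items()}


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.astype(np.float64), ys.astype(np.float64)


def _blob(xs, ys, cx, cy, sigma):
    return np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma**2))


def _stroke(xs, ys, p0, p1, sigma):
    """Gaussian falloff of the distance to the segment p0-p1."""
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    length2 = vx * vx + vy * vy
    if length2 == 0:
        return _blob(xs, ys, p0[0], p0[1], sigma)
    t = np.clip(((xs - p0[0]) * vx + (ys - p0[1]) * vy) / length2, 0.0, 1.0)
    dx = xs - (p0[0] + t * vx)
    dy = ys - (p0[1] + t * vy)
    return np.exp(-(dx * dx + dy * dy) / (2.0 * sigma**2))


def _render_frame(
    spec: FaceSpec,
    markers: Mapping[str, tuple[float, float]],
    center: tuple[float, float],
    texture: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
) -> np.ndarray:
    geom = spec.geometry()
    a, b = geom.semi_axis_x, geom.semi_axis_y
    cx, cy = geom.center
    q = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2
    face = np.clip((1.0 - q) / 0.05, 0.0, 1.0)  # soft-edged ellipse mask
    img = spec.background + (spec.face_albedo - spec.background) * face
    img += texture * face
    # eyes (static)
    for ex, ey in (spec.left_eye, spec.right_eye):
        img -= 150.0 * _blob(xs, ys, ex, ey, 3.5)
    # brows: strokes between the inner (65 deg) and outer (45 deg)
    # eyebrow markers, moving with them
    img -= 60.0 * _stroke(xs, ys, markers["p_e3"], markers["p_e1"], 2.0)
    img -= 60.0 * _stroke(xs, ys, markers["p_e4"], markers["p_e2"], 2.0)
    # mouth: elliptical outline through the four mouth markers
    mx = 0.5 * (markers["p_m1"][0] + markers["p_m2"][0])
    my = 0.5 * (markers["p_m3"][1] + markers["p_m4"][1])
    ax = max(0.5 * abs(markers["p_m2"][0] - markers["p_m1"][0]), 2.0)
    ay = max(0.5 * abs(markers["p_m4"][1] - markers["p_m3"][1]), 2.0)
    qm = np.sqrt(((xs - mx) / ax) ** 2 + ((ys - my) / ay) ** 2)
    ring_w = 1.5 / min(ax, ay)
    img -= 50.0 * np.exp(-((qm - 1.0) ** 2) / (2.0 * ring_w**2))
    # virtual-marker dots and the centre mark
    for mid in MARKER_IDS:
        img -= 80.0 * _blob(xs, ys, *markers[mid], 2.5)
    img -= 80.0 * _blob(xs, ys, *center, 2.5)
    return img


def ground_truth_trajectories(
    spec: FaceSpec, emotion_field: EmotionField, n_frames: int
) -> dict[str, np.ndarray]:
    """Noise-free marker trajectories, (n_frames, 2) per marker id
    plus the (static) centre."""
    base = spec.base_markers()
    profile = emotion_field.profile(n_frames)
    iod = spec.interocular
    truth: dict[str, np.ndarray] = {}
    for mid in MARKER_IDS:
        x0, y0 = base.markers[mid]
        dx, dy = emotion_field.apex(mid)
        truth[mid] = np.column_stack(
            [x0 + profile * dx * iod, y0 + profile * dy * iod]
        )
    cx, cy = base.center
    truth[CENTER_ID] = np.column_stack(
        [np.full(n_frames, cx), np.full(n_frames, cy)]
    )
    return truth


def render_sequence(
    spec: FaceSpec,
    emotion_field: EmotionField,
    n_frames: int,
    seed: int = 0,
) -> tuple[FrameSequence, dict[str, np.ndarray]]:
    """Render an expression sequence with ground-truth trajectories.

    Frame 0 is the neutral face; the deformation follows the
    template's ramp-and-hold profile.  Rendering is deterministic per
    seed.  Raises :class:`GenerationError` when a template would push
    a marker outside the trackable image area.
    """
    if n_frames < 2:
        raise GenerationError("need at least 2 frames")
    h, w = spec.image_size
    truth = ground_truth_trajectories(spec, emotion_field, n_frames)
    margin = 10.0
    for mid, traj in truth.items():
        if (traj[:, 0].min() < margin or traj[:, 0].max() > w - 1 - margin
                or traj[:, 1].min() < margin or traj[:, 1].max() > h - 1 - margin):
            raise GenerationError(
                f"marker {mid} leaves the image under template "
                f"{emotion_field.label!r}"
            )
    xs, ys = _grid((h, w))
    tex_rng = np.random.default_rng(spec.texture_seed)
    texture = ndimage.gaussian_filter(tex_rng.standard_normal((h, w)), 3.0)
    texture *= spec.texture_amp / max(texture.std(), 1e-12)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w))
    center = tuple(truth[CENTER_ID][0])
    for t in range(n_frames):
        markers = {mid: tuple(truth[mid][t]) for mid in MARKER_IDS}
        img = _render_frame(spec, markers, center, texture, xs, ys)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        frames[t] = np.clip(img, 0.0, 255.0)
    seq = FrameSequence(frames, frame_rate=30.0,
                        source_id=f"synthface:{emotion_field.label}")
    return seq, truth


@dataclass
class TrialRecord:
    """One simulated trial: tracked landmark states plus metadata."""

    label: str
    subject_id: str
    trial_id: str
    states: list[TrackState]


def simulate_trajectory_collection(
    fields: Mapping[str, EmotionField] | None = None,
    *,
    n_subjects: int = 30,
    trials_per_emotion: int = 2,
    sigma_marker: float = 0.5,
    sigma_scale: float = 0.15,
    n_frames: int = 61,
    seed: int = 0,
    spec: FaceSpec | None = None,
) -> list[TrialRecord]:
    """Landmark-space trial simulation at the emulated study scale.

    Each trial is template motion scaled by a per-subject lognormal
    expressiveness factor (sigma ``sigma_scale`` in log space) plus
    i.i.d. Gaussian per-frame jitter of ``sigma_marker`` pixels on
    every landmark, including the centre.
    """
    fields = fields or default_emotion_fields()
    if len(fields) != 6:
        raise GenerationError("six emotion templates expected")
    spec = spec or FaceSpec()
    base = spec.base_markers()
    iod = spec.interocular
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        expressiveness = float(np.exp(rng.normal(0.0, sigma_scale)))
        for label in sorted(fields):
            fld = fields[label]
            profile = fld.profile(n_frames)
            for trial in range(trials_per_emotion):
                states = []
                jitter = rng.normal(0.0, sigma_marker,
                                    size=(n_frames, len(MARKER_IDS) + 1, 2))
                for t in range(n_frames):
                    positions = {}
                    for i, mid in enumerate(MARKER_IDS):
                        x0, y0 = base.markers[mid]
                        dx, dy = fld.apex(mid)
                        positions[mid] = (
                            x0 + expressiveness * profile[t] * dx * iod
                            + jitter[t, i, 0],
                            y0 + expressiveness * profile[t] * dy * iod
                            + jitter[t, i, 1],
                        )
                    positions[CENTER_ID] = (
                        base.center[0] + jitter[t, -1, 0],
                        base.center[1] + jitter[t, -1, 1],
                    )
                    states.append(TrackState(t, positions))
                records.append(
                    TrialRecord(label, subject, f"t{trial + 1}", states)
                )
    return records


def build_trial_set(
    records: Sequence[TrialRecord],
    mode: str = "CMD",
    statistic: str = "rms",
    *,
    baseline_frames: int = 1,
) -> LabeledTrialSet:
    """Convert simulated trials into a labelled feature set."""
    X, y, subjects = [], [], []
    for rec in records:
        if mode == "MD":
            series = md_series(rec.states)
        else:
            series = cmd_series(rec.states, baseline_frames=baseline_frames)
        tf = trial_statistics(series, statistic, mode=mode, label=rec.label,
                              subject_id=rec.subject_id, trial_id=rec.trial_id)
        X.append(tf.values)
        y.append(rec.label)
        subjects.append(rec.subject_id)
    return LabeledTrialSet(np.array(X), np.array(y), np.array(subjects))


def rendered_trial_features(
    fields: Mapping[str, EmotionField] | None = None,
    *,
    seeds: Sequence[int] = (0, 1, 2),
    n_frames: int = 15,
    spec: FaceSpec | None = None,
    mode: str = "CMD",
    statistic: str = "rms",
):
    """Render, track and featurize one trial per emotion and seed.

    Unlike the landmark-space simulator this path goes through the
    actual renderer and Lucas-Kanade tracker, so the resulting feature
    vectors carry the measurement biases of the full pipeline; use it
    to train models that will classify tracked sequences.
    """
    from .features import TrialFeatures
    from .lktrack import TrackerConfig, track_sequence

    fields = fields or default_emotion_fields()
    spec = spec or FaceSpec()
    out: list[TrialFeatures] = []
    for label in sorted(fields):
        for seed in seeds:
            seq, _ = render_sequence(spec, fields[label], n_frames, seed=seed)
            states = track_sequence(seq, spec.base_markers(), TrackerConfig())
            if mode == "MD":
                series = md_series(states)
            else:
                series = cmd_series(states)
            out.append(
                trial_statistics(series, statistic, mode=mode, label=label,
                                 subject_id=f"seed{seed}", trial_id="r1")
            )
    return out


def simulate_trials(
    fields: Mapping[str, EmotionField] | None = None,
    *,
    n_subjects: int = 30,
    trials_per_emotion: int = 2,
    sigma_marker: float = 0.5,
    sigma_scale: float = 0.15,
    n_frames: int = 61,
    seed: int = 0,
    mode: str = "CMD",
    statistic: str = "rms",
) -> LabeledTrialSet:
    """Simulate labelled trials ready for cross-validation."""
    records = simulate_trajectory_collection(
        fields, n_subjects=n_subjects, trials_per_emotion=trials_per_emotion,
        sigma_marker=sigma_marker, sigma_scale=sigma_scale,
        n_frames=n_frames, seed=seed,
    )
    return build_trial_set(records, mode=mode, statistic=statistic)
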