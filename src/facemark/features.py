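"""Distance features and per-trial statistics.

Two feature modes are supported:

* **MD** (marker distance): per frame, the Euclidean distance of each
  of the eight markers to the face centre, plus the mouth width (the
  distance between the left and right mouth-corner markers) as a ninth
  feature.
* **CMD** (change in marker distance): the per-frame MD vector minus a
  neutral baseline taken from the first frame(s) of the trial.  Signed
  differences are kept by default so the direction of motion (e.g.
  brow raise vs. lowering) is preserved; an absolute-value mode is
  available.

A trial (one expression sequence) is summarized by applying a
statistic — mean, RMS, or sample variance — independently per feature
dimension over frames, giving a 9-vector per trial.  Min-max
normalization (binary to [0, 1], bipolar to [-1, 1]) is fitted on
training data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import marker_distance
from .lktrack import CENTER_ID, TrackState

#: Feature order: four eyebrow distances, four mouth distances, mouth width.
FEATURE_NAMES: tuple[str, ...] = (
    "e1", "e2", "e3", "e4", "m1", "m2", "m3", "m4", "m5",
)

_MARKER_FOR_FEATURE = {
    "e1": "p_e1", "e2": "p_e2", "e3": "p_e3", "e4": "p_e4",
    "m1": "p_m1", "m2": "p_m2", "m3": "p_m3", "m4": "p_m4",
}

STATISTICS = ("mean", "rms", "variance")
MODES = ("MD", "CMD")
SCHEMES = ("none", "binary", "bipolar")


class FeatureError(ValueError):
    pass


@dataclass
class DistanceFeatures:
    """The nine distance features for one frame, in pixels."""

    frame_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (9,):
            raise FeatureError("expected 9 feature values")


@dataclass
class TrialFeatures:
    """A statistic of the distance features over one trial."""

    statistic: str
    mode: str
    values: np.ndarray
    label: str | None = None
    subject_id: str | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (9,):
            raise FeatureError("expected 9 feature values")
        if self.statistic not in STATISTICS:
            raise FeatureError(f"unknown statistic {self.statistic!r}")
        if self.mode not in MODES:
            raise FeatureError(f"unknown mode {self.mode!r}")


def _frame_centers(
    states: Sequence[TrackState],
    centers: Sequence[tuple[float, float]] | None,
) -> list[tuple[float, float]]:
    if centers is not None:
        if len(centers) != len(states):
            raise FeatureError("need one centre per frame")
        return list(centers)
    out = []
    for st in states:
        if CENTER_ID not in st.positions:
            raise FeatureError(
                "no tracked centre point; pass explicit per-frame centres"
            )
        out.append(st.positions[CENTER_ID])
    return out


def md_series(
    states: Sequence[TrackState],
    centers: Sequence[tuple[float, float]] | None = None,
) -> list[DistanceFeatures]:
    """Marker-distance features for every frame of a tracked sequence.

    The centre is taken from the tracked ``center`` point unless
    explicit per-frame centres are given (e.g. recomputed from
    re-detected eyes).
    """
    if not states:
        raise FeatureError("empty track sequence")
    ctrs = _frame_centers(states, centers)
    out = []
    for st, c in zip(states, ctrs):
        vals = np.empty(9)
        for i, feat in enumerate(FEATURE_NAMES[:8]):
            mid = _MARKER_FOR_FEATURE[feat]
            if mid not in st.positions:
                raise FeatureError(f"marker {mid} missing at frame {st.frame_index}")
            vals[i] = marker_distance(c, st.positions[mid])
        vals[8] = marker_distance(st.positions["p_m1"], st.positions["p_m2"])
        out.append(DistanceFeatures(st.frame_index, vals))
    return out


def baseline_from(series: Sequence[DistanceFeatures], k: int = 1) -> DistanceFeatures:
    """Neutral baseline: mean of the first ``k`` frames' MD vectors."""
    if k < 1 or k > len(series):
        raise FeatureError(f"baseline window k={k} outside [1, {len(series)}]")
    vals = np.mean([s.values for s in series[:k]], axis=0)
    return DistanceFeatures(series[0].frame_index, vals)


def cmd_series(
    states: Sequence[TrackState],
    centers: Sequence[tuple[float, float]] | None = None,
    baseline: DistanceFeatures | None = None,
    *,
    baseline_frames: int = 1,
    absolute: bool = False,
) -> list[DistanceFeatures]:
    """Change-in-marker-distance features relative to a neutral baseline.

    If no explicit ``baseline`` is given it is computed from the first
    ``baseline_frames`` frames of the same sequence.
    """
    md = md_series(states, centers)
    if baseline is None:
        baseline = baseline_from(md, k=baseline_frames)
    out = []
    for s in md:
        delta = s.values - baseline.values
        if absolute:
            delta = np.abs(delta)
        out.append(DistanceFeatures(s.frame_index, delta))
    return out


def trial_statistics(
    series: Sequence[DistanceFeatures],
    statistic: str,
    *,
    mode: str = "MD",
    label: str | None = None,
    subject_id: str | None = None,
    trial_id: str | None = None,
) -> TrialFeatures:
    """Summarize a per-frame feature series with one statistic.

    mean is the arithmetic mean, rms the root of the mean square, and
    variance the sample variance (n-1 denominator); variance therefore
    needs at least two frames.
    """
    if statistic not in STATISTICS:
        raise FeatureError(f"unknown statistic {statistic!r}")
    n = len(series)
    if n < 1 or (statistic == "variance" and n < 2):
        raise FeatureError(f"too few frames ({n}) for statistic {statistic!r}")
    mat = np.stack([s.values for s in series])
    if statistic == "mean":
        vals = mat.mean(axis=0)
    elif statistic == "rms":
        vals = np.sqrt(np.mean(mat**2, axis=0))
    else:
        vals = mat.var(axis=0, ddof=1)
    return TrialFeatures(statistic, mode, vals, label=label,
                         subject_id=subject_id, trial_id=trial_id)


@dataclass
class NormalizationSpec:
    """Per-dimension min-max normalization fitted on training data.

    binary maps the training range to [0, 1]; bipolar to [-1, 1].
    Dimensions constant in training map to 0 under both schemes.
    """

    scheme: str
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise FeatureError(f"unknown normalization scheme {self.scheme!r}")

    def fit(self, x: np.ndarray) -> "NormalizationSpec":
        x = np.asarray(x, dtype=np.float64)
        self.mins = x.min(axis=0)
        self.maxs = x.max(axis=0)
        return self

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.scheme == "none":
            return x.copy()
        if self.mins is None or self.maxs is None:
            raise FeatureError("normalization applied before fitting")
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        unit = (x - self.mins) / safe
        if self.scheme == "binary":
            out = unit
            out = np.where(span > 0, out, 0.0)
        else:  # bipolar
            out = 2.0 * unit - 1.0
            out = np.where(span > 0, out, 0.0)
        return out


def fit_apply_normalization(
    train: np.ndarray, test: np.ndarray, scheme: str
) -> tuple[np.ndarray, np.ndarray, NormalizationSpec]:
    """Fit min-max statistics on ``train`` only and apply to both sets."""
    if len(train) == 0:
        raise FeatureError("empty training set")
    spec = NormalizationSpec(scheme).fit(train)
    return spec.apply(train), spec.apply(test), spec


def trials_to_frame(trials: Iterable[TrialFeatures]) -> pd.DataFrame:
    """Tabulate trial features: subject, trial, emotion, mode,
    statistic, e1..m5."""
    rows = []
    for t in trials:
        row = {"subject": t.subject_id, "trial": t.trial_id,
               "emotion": t.label, "mode": t.mode, "statistic": t.statistic}
        row.update(dict(zip(FEATURE_NAMES, t.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> list[TrialFeatures]:
    """Inverse of :func:`trials_to_frame`."""
    out = []
    for _, row in df.iterrows():
        out.append(
            TrialFeatures(
                statistic=row["statistic"], mode=row["mode"],
                values=row[list(FEATURE_NAMES)].to_numpy(dtype=np.float64),
                label=row.get("emotion"), subject_id=row.get("subject"),
                trial_id=str(row.get("trial")),
            )
        )
    return out


def write_trials(path, trials: Iterable[TrialFeatures]) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path) -> list[TrialFeatures]:
    return frame_to_trials(pd.read_csv(path))
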