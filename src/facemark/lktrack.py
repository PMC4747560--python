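"""Pyramidal Lucas–Kanade point tracking.

Tracks the eight virtual markers (and the face centre) from frame to
frame by solving, per point, the 2x2 least-squares system built from
spatial and temporal intensity gradients inside a square window:

    G d = b,   G = sum [Ix^2, IxIy; IxIy, Iy^2],  b = -sum It [Ix, Iy]

iterated to convergence, coarse-to-fine over a Gaussian image pyramid.
A point is flagged lost when the structure tensor is near-singular
(textureless window), the iteration diverges, or the point leaves the
valid border margin.  Intensities are normalized to [0, 1] internally
so the eigenvalue threshold is independent of the input bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .acquisition import FrameSequence
from .geometry import MarkerSet

OK = "ok"
LOST = "lost"

#: Point id under which the face centre is tracked alongside markers.
CENTER_ID = "center"


@dataclass
class TrackerConfig:
    window: int = 15          # window side length, odd, pixels
    levels: int = 3           # pyramid levels (1 = no pyramid)
    max_iter: int = 20        # LK iterations per level
    eps: float = 0.01         # convergence threshold, pixels
    eigen_threshold: float = 1e-4   # min eigenvalue of G / window area
    track_center: bool = True  # track the centre point like a marker

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.levels < 1:
            raise ValueError("at least one pyramid level required")


@dataclass
class TrackState:
    """Tracked positions and per-point status for one frame."""

    frame_index: int
    positions: dict[str, tuple[float, float]]
    status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (x, y) in self.positions.items():
            st = self.status.setdefault(pid, OK)
            if st == OK and not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite position for ok point {pid}")


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    # bilinear interpolation; map_coordinates takes (row, col) order
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    levels_out = [np.asarray(frame, dtype=np.float64) / 255.0]
    for _ in range(levels - 1):
        prev = levels_out[-1]
        if min(prev.shape) < 16:
            break
        smoothed = ndimage.gaussian_filter(prev, sigma=1.0)
        levels_out.append(smoothed[::2, ::2])
    return levels_out


def _window_offsets(window: int) -> tuple[np.ndarray, np.ndarray]:
    half = window // 2
    off = np.arange(-half, half + 1, dtype=np.float64)
    ox, oy = np.meshgrid(off, off)
    return ox.ravel(), oy.ravel()


def _lk_level(
    prev: np.ndarray,
    nxt: np.ndarray,
    point: np.ndarray,
    guess: np.ndarray,
    cfg: TrackerConfig,
) -> tuple[np.ndarray, bool]:
    """One LK solve at a single pyramid level (images in [0, 1])."""
    h, w = prev.shape
    half = cfg.window // 2
    margin = half + 1
    x0, y0 = point
    if not (margin <= x0 <= w - 1 - margin and margin <= y0 <= h - 1 - margin):
        return guess, False
    ox, oy = _window_offsets(cfg.window)
    xs, ys = x0 + ox, y0 + oy
    # spatial gradients of the previous frame via central differences
    ix = 0.5 * (_sample(prev, xs + 1, ys) - _sample(prev, xs - 1, ys))
    iy = 0.5 * (_sample(prev, xs, ys + 1) - _sample(prev, xs, ys - 1))
    template = _sample(prev, xs, ys)
    g = np.array([[np.sum(ix * ix), np.sum(ix * iy)],
                  [np.sum(ix * iy), np.sum(iy * iy)]])
    n_pix = float(len(ox))
    eigvals = np.linalg.eigvalsh(g)
    if eigvals[0] / n_pix < cfg.eigen_threshold:
        return guess, False
    d = guess.astype(np.float64).copy()
    for _ in range(cfg.max_iter):
        it = _sample(nxt, xs + d[0], ys + d[1]) - template
        b = -np.array([np.sum(it * ix), np.sum(it * iy)])
        step = np.linalg.solve(g, b)
        d += step
        if np.hypot(*step) < cfg.eps:
            break
        if np.hypot(*d) > cfg.window * 2:
            return guess, False
    return d, True


def lk_step(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    point: tuple[float, float],
    *,
    window: int = 15,
    levels: int = 1,
    max_iter: int = 20,
    eps: float = 0.01,
    eigen_threshold: float = 1e-4,
) -> tuple[float, float, str]:
    """Estimate the flow of one point between two frames.

    Returns ``(dx, dy, status)`` where status is ``"ok"`` or
    ``"lost"``.  Points within the window margin of the border, or in
    textureless (singular structure tensor) regions, come back lost
    with zero displacement.
    """
    cfg = TrackerConfig(window=window, levels=levels, max_iter=max_iter,
                        eps=eps, eigen_threshold=eigen_threshold)
    d, ok = _track_point(
        _pyramid(prev_frame, cfg.levels), _pyramid(next_frame, cfg.levels),
        np.asarray(point, dtype=np.float64), cfg,
    )
    if not ok:
        return (0.0, 0.0, LOST)
    return (float(d[0]), float(d[1]), OK)


def _track_point(
    prev_pyr: list[np.ndarray],
    next_pyr: list[np.ndarray],
    point: np.ndarray,
    cfg: TrackerConfig,
) -> tuple[np.ndarray, bool]:
    levels = min(len(prev_pyr), len(next_pyr))
    d = np.zeros(2)
    ok_any = False
    for lv in range(levels - 1, -1, -1):
        scaled = point / (2.0 ** lv)
        d, ok = _lk_level(prev_pyr[lv], next_pyr[lv], scaled, d, cfg)
        ok_any = ok_any or ok
        if lv > 0:
            d = d * 2.0
    # the finest level must succeed for the point to count as tracked
    return d, ok


def track_sequence(
    seq: FrameSequence,
    initial: MarkerSet,
    config: TrackerConfig | None = None,
) -> list[TrackState]:
    """Track the markers of ``initial`` through a frame sequence.

    Returns one :class:`TrackState` per frame (the first mirrors the
    initial placement).  Lost markers hold their last good position and
    stay flagged for the rest of the sequence.
    """
    cfg = config or TrackerConfig()
    points: dict[str, tuple[float, float]] = dict(initial.markers)
    if cfg.track_center:
        points[CENTER_ID] = initial.center
    status = {pid: OK for pid in points}
    states = [TrackState(0, dict(points), dict(status))]
    if len(seq) < 2:
        return states
    pyramids = [_pyramid(seq[i], cfg.levels) for i in range(len(seq))]
    for fi in range(1, len(seq)):
        prev_pyr, next_pyr = pyramids[fi - 1], pyramids[fi]
        new_points = {}
        for pid, (x, y) in points.items():
            if status[pid] == LOST:
                new_points[pid] = (x, y)
                continue
            d, ok = _track_point(prev_pyr, next_pyr,
                                 np.array([x, y]), cfg)
            if ok:
                new_points[pid] = (x + float(d[0]), y + float(d[1]))
            else:
                new_points[pid] = (x, y)
                status[pid] = LOST
        points = new_points
        states.append(TrackState(fi, dict(points), dict(status)))
    return states


def write_trajectories(path, states: Iterable[TrackState]) -> None:
    """CSV writer: ``frame,marker_id,x,y,status``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "marker_id", "x", "y", "status"])
        for st in states:
            for pid in sorted(st.positions):
                x, y = st.positions[pid]
                writer.writerow(
                    [st.frame_index, pid, f"{x:.6f}", f"{y:.6f}", st.status[pid]]
                )
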