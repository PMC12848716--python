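"""Sliding-window segmentation of trajectories.

Each trajectory is cut into fixed-length overlapping windows; a window is
labeled by the ground-truth motion type at its center frame, so windows
spanning a motion switch inherit the regime that governs their middle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .simulate import InvalidParameterError, Trajectory3D

__all__ = ["WindowSample", "WindowStack", "segment", "segment_dataset", "window_count"]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 29
DEFAULT_STEP = 1


@dataclass
class WindowSample:
    """One fixed-length trajectory segment with its center-frame label."""

    source_id: str
    start: int
    pos: np.ndarray  # (W, 3)
    t: np.ndarray  # (W,)
    center_label: str

    @property
    def window(self) -> int:
        return len(self.t)

    @property
    def center(self) -> int:
        return self.start + (self.window - 1) // 2


@dataclass
class WindowStack:
    """A batch of equally sized windows stored as dense arrays.

    ``pos`` has shape (n_windows, W, 3).  ``source_class`` carries the
    trajectory-level class of each window's parent (used for stratified
    grouped splitting); ``center_label`` is the per-window target.
    """

    pos: np.ndarray
    t0: np.ndarray
    dt: float
    start: np.ndarray
    source_id: np.ndarray
    source_class: np.ndarray
    center_label: np.ndarray

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def window(self) -> int:
        return self.pos.shape[1]


def window_count(n_frames: int, window: int, step: int) -> int:
    """Number of windows: floor((N - W) / step) + 1 (0 when W > N)."""
    if window > n_frames:
        return 0
    return (n_frames - window) // step + 1


def _validate(window: int, step: int) -> None:
    if window % 2 == 0:
        raise InvalidParameterError("window length must be odd (unambiguous center)")
    if window < 3:
        raise InvalidParameterError("window length must be >= 3")
    if step < 1:
        raise InvalidParameterError("step must be >= 1")


def segment(
    traj: Trajectory3D, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[WindowSample]:
    """Cut one trajectory into overlapping windows labeled at their centers.

    Trajectories shorter than the window are skipped with a logged warning
    (returning an empty list) so short extracted tracks never abort a batch.
    """
    _validate(window, step)
    n = traj.n_frames
    if window > n:
        logger.warning(
            "trajectory %s has %d frames < window %d; skipped", traj.id, n, window
        )
        return []
    half = (window - 1) // 2
    out = []
    for start in range(0, n - window + 1, step):
        out.append(
            WindowSample(
                source_id=traj.id,
                start=start,
                pos=traj.pos[start : start + window],
                t=traj.t[start : start + window],
                center_label=str(traj.labels[start + half]),
            )
        )
    return out


def segment_dataset(
    trajs: Iterable[Trajectory3D], window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> WindowStack:
    """Segment many trajectories into one dense :class:`WindowStack`.

    Equivalent to concatenating :func:`segment` over all trajectories but
    stored as a (n_windows, W, 3) array for vectorized feature extraction.
    """
    _validate(window, step)
    half = (window - 1) // 2
    pos_parts: list[np.ndarray] = []
    meta: list[tuple[np.ndarray, str, str, np.ndarray]] = []
    dt = None
    for traj in trajs:
        n = traj.n_frames
        if window > n:
            logger.warning(
                "trajectory %s has %d frames < window %d; skipped", traj.id, n, window
            )
            continue
        if dt is None and n > 1:
            dt = float(traj.t[1] - traj.t[0])
        starts = np.arange(0, n - window + 1, step)
        views = sliding_window_view(traj.pos, window, axis=0)[::step]  # (k, 3, W)
        pos_parts.append(np.ascontiguousarray(views.transpose(0, 2, 1)))
        centers = traj.labels[starts + half].astype(object)
        meta.append((starts, traj.id, traj.motion_class, centers))
    if not pos_parts:
        return WindowStack(
            pos=np.empty((0, window, 3)),
            t0=np.empty(0),
            dt=dt or 0.0,
            start=np.empty(0, dtype=int),
            source_id=np.empty(0, dtype=object),
            source_class=np.empty(0, dtype=object),
            center_label=np.empty(0, dtype=object),
        )
    starts_all = np.concatenate([m[0] for m in meta])
    ids = np.concatenate([np.full(len(m[0]), m[1], dtype=object) for m in meta])
    classes = np.concatenate([np.full(len(m[0]), m[2], dtype=object) for m in meta])
    labels = np.concatenate([m[3] for m in meta])
    return WindowStack(
        pos=np.concatenate(pos_parts, axis=0),
        t0=starts_all * (dt or 0.0),
        dt=dt or 0.0,
        start=starts_all,
        source_id=ids,
        source_class=classes,
        center_label=labels,
    )
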