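"""Monte Carlo simulation of labeled 3D single-particle trajectories.

Five motion regimes are generated: directed motion (DM), normal Brownian
diffusion (ND), anomalous subdiffusion (AD, Weierstrass-Mandelbrot model),
confined diffusion (CD, hard reflecting sphere via rejection sampling) and
mixed motion (MM, segment-wise switching among the four pure regimes).
Positions are in micrometres, times in seconds.  Every trajectory carries a
per-frame ground-truth label from {DM, ND, AD, CD}.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MOTION_LABELS",
    "TRAJECTORY_CLASSES",
    "Trajectory3D",
    "SimulationConfig",
    "MsdCurve",
    "InvalidParameterError",
    "SimulationStallError",
    "simulate_nd",
    "simulate_dm",
    "simulate_ad",
    "simulate_cd",
    "simulate_mm",
    "generate_dataset",
    "empirical_msd",
    "theoretical_msd",
    "wm_function",
]

#: Canonical per-frame label order used everywhere downstream (tie-breaks,
#: confusion matrices, report columns).
MOTION_LABELS = ("DM", "ND", "AD", "CD")

#: Trajectory-level classes: the four pure regimes plus mixed motion.
TRAJECTORY_CLASSES = ("DM", "ND", "AD", "CD", "MM")


class InvalidParameterError(ValueError):
    """A simulation parameter is outside its admissible range."""


class SimulationStallError(RuntimeError):
    """Confined-diffusion rejection sampling exceeded its attempt cap."""


@dataclass
class Trajectory3D:
    """A time-ordered 3D track with per-frame ground-truth motion labels.

    Attributes
    ----------
    id : str
        Trajectory identifier, unique within a dataset.
    t : ndarray, shape (N,)
        Strictly increasing frame times in seconds.
    pos : ndarray, shape (N, 3)
        Positions (x, y, z) in micrometres; origin-anchored (pos[0] == 0).
    labels : ndarray of str, shape (N,)
        Per-frame motion label, each in :data:`MOTION_LABELS`.
    motion_class : str
        Trajectory-level class in :data:`TRAJECTORY_CLASSES` ("MM" when the
        frame labels are not all identical).
    """

    id: str
    t: np.ndarray
    pos: np.ndarray
    labels: np.ndarray
    motion_class: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.t)
        if self.pos.shape != (n, 3):
            raise InvalidParameterError(
                f"pos shape {self.pos.shape} does not match {n} time points"
            )
        if len(self.labels) != n:
            raise InvalidParameterError("labels length does not match time points")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise InvalidParameterError("t must be strictly increasing")
        if not np.all(np.isfinite(self.pos)):
            raise InvalidParameterError("non-finite coordinates")
        if not self.motion_class:
            uniq = set(self.labels.tolist())
            self.motion_class = uniq.pop() if len(uniq) == 1 else "MM"

    @property
    def n_frames(self) -> int:
        return len(self.t)


@dataclass
class SimulationConfig:
    """Dataset-level simulation parameters.

    Defaults define the reference study conditions: 5000 trajectories of 100
    frames at 20 Hz (dt = 0.05 s), diffusivities 0.1-1.0 um^2/s, directed
    speed coefficient 5-20 (speed = coef * D), anomalous exponent 0.3-0.7,
    confinement parameter B 1-10 (radius r = (D*B)^(1/3)), mixed-motion
    segments of 20-50 frames, and a class mix of 18% each pure regime plus
    28% mixed motion.
    """

    n_trajectories: int = 5000
    n_frames: int = 100
    dt: float = 0.05
    D_range: tuple[float, float] = (0.1, 1.0)
    coef_range: tuple[float, float] = (5.0, 20.0)
    alpha_range: tuple[float, float] = (0.3, 0.7)
    B_range: tuple[float, float] = (1.0, 10.0)
    mm_segment_range: tuple[int, int] = (20, 50)
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"DM": 0.18, "ND": 0.18, "AD": 0.18, "CD": 0.18, "MM": 0.28}
    )
    dm_angular_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D_range", "coef_range", "alpha_range", "B_range", "mm_segment_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidParameterError(f"{name} lower bound exceeds upper bound")
        if not (0.0 < self.alpha_range[0] and self.alpha_range[1] < 1.0):
            raise InvalidParameterError("alpha_range must be a subinterval of (0, 1)")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise InvalidParameterError(f"class_mix sums to {total}, expected 1")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be at least 2")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class MsdCurve:
    """Mean squared displacement versus lag.

    ``lags`` are positive frame counts (strictly increasing); ``values`` are
    the corresponding MSDs in um^2.
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.lags) != len(self.values):
            raise InvalidParameterError("lags and values length mismatch")
        if len(self.lags) > 1 and not np.all(np.diff(self.lags) > 0):
            raise InvalidParameterError("lags must be strictly increasing")
        if np.any(self.values < -1e-12):
            raise InvalidParameterError("MSD values must be non-negative")


def _times(n_frames: int, dt: float) -> np.ndarray:
    return np.arange(n_frames) * dt


def _check_common(n_frames: int, dt: float) -> None:
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")


# ---------------------------------------------------------------------------
# Normal diffusion
# ---------------------------------------------------------------------------

def simulate_nd(
    n_frames: int, dt: float, D: float, rng: np.random.Generator, traj_id: str = "nd"
) -> Trajectory3D:
    """Simulate free Brownian motion in 3D.

    Per-axis displacements are i.i.d. Gaussian with zero mean and standard
    deviation sqrt(2*D*dt); the trajectory is their cumulative sum starting
    at the origin, giving ensemble MSD(t) = 6*D*t.
    """
    _check_common(n_frames, dt)
    if D <= 0:
        raise InvalidParameterError("D must be positive")
    sigma = math.sqrt(2.0 * D * dt)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return Trajectory3D(traj_id, _times(n_frames, dt), pos, np.full(n_frames, "ND", dtype=object))


# ---------------------------------------------------------------------------
# Directed motion
# ---------------------------------------------------------------------------

def simulate_dm(
    n_frames: int,
    dt: float,
    D: float,
    coef_range: tuple[float, float],
    rng: np.random.Generator,
    traj_id: str = "dm",
    angular_noise: float = 1.0,
    speed: float | None = None,
) -> Trajectory3D:
    """Simulate directed (drift-dominated) motion in 3D.

    The particle drifts with speed ``coef * D`` (coef uniform in
    ``coef_range``) along a direction whose azimuthal and polar angles
    perform a Wiener process (increments N(0, angular_noise * D * dt)),
    superimposed on a normal-diffusion displacement with the same D.

    ``speed`` overrides the sampled coef*D product; ``angular_noise = 0``
    freezes the direction (useful as a noise-free limit).
    """
    _check_common(n_frames, dt)
    lo, hi = coef_range
    if lo <= 0 or hi <= 0 or lo > hi:
        raise InvalidParameterError("coef_range must be a positive, ordered interval")
    if speed is None:
        speed = float(rng.uniform(lo, hi)) * D
    n_steps = n_frames - 1
    v0 = rng.normal(size=3)
    norm = np.linalg.norm(v0)
    if norm == 0:  # pragma: no cover - probability zero
        v0 = np.array([1.0, 0.0, 0.0])
        norm = 1.0
    v0 /= norm
    phi = math.atan2(v0[1], v0[0])
    theta = math.acos(np.clip(v0[2], -1.0, 1.0))
    ang_sd = math.sqrt(max(angular_noise * D * dt, 0.0))
    dphi = rng.normal(0.0, ang_sd, size=n_steps) if ang_sd > 0 else np.zeros(n_steps)
    dtheta = rng.normal(0.0, ang_sd, size=n_steps) if ang_sd > 0 else np.zeros(n_steps)
    phis = phi + np.cumsum(dphi)
    thetas = theta + np.cumsum(dtheta)
    dirs = np.column_stack(
        [np.sin(thetas) * np.cos(phis), np.sin(thetas) * np.sin(phis), np.cos(thetas)]
    )
    drift_steps = speed * dt * dirs
    if D > 0:
        diff_steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(n_steps, 3))
    else:
        diff_steps = np.zeros((n_steps, 3))
    pos = np.vstack([np.zeros(3), np.cumsum(drift_steps + diff_steps, axis=0)])
    return Trajectory3D(traj_id, _times(n_frames, dt), pos, np.full(n_frames, "DM", dtype=object))


# ---------------------------------------------------------------------------
# Anomalous subdiffusion (Weierstrass-Mandelbrot)
# ---------------------------------------------------------------------------

_WM_N = np.arange(-8, 49)  # Saxton summation range
_WM_GAMMA = math.sqrt(math.pi)


def wm_function(tstar: np.ndarray, alpha: float, phases: np.ndarray) -> np.ndarray:
    """Evaluate the Weierstrass-Mandelbrot sum W(t*) for given phases.

    W(t*) = sum_{n=-8}^{48} [cos(phi_n) - cos(gamma^n t* + phi_n)] / gamma^(n alpha / 2)
    with gamma = sqrt(pi).  The random-phase version (phi_n uniform on
    [0, 2pi)) yields a stationary-increment series whose increment variance
    grows as t^alpha over the scaling regime.
    """
    tstar = np.asarray(tstar, dtype=float)
    g = _WM_GAMMA ** _WM_N
    amp = _WM_GAMMA ** (_WM_N * alpha / 2.0)
    args = np.multiply.outer(tstar, g) + phases
    return ((np.cos(phases) - np.cos(args)) / amp).sum(axis=-1)


def simulate_ad(
    n_frames: int,
    dt: float,
    D: float,
    alpha: float,
    rng: np.random.Generator,
    traj_id: str = "ad",
    oversample: int = 2,
) -> Trajectory3D:
    """Simulate anomalous subdiffusion via the Weierstrass-Mandelbrot series.

    Each axis is an independent WM increment series: N = oversample * N0
    points are generated on t* = 2*pi*t/N, the function is subsampled at
    stride ``oversample`` (which preserves the long-range increment
    correlations responsible for the t**alpha scaling), and the axis is
    rescaled so the per-step displacement variance equals 2*D*dt**alpha
    (the per-axis share of the target ensemble law MSD(t) = 6*D*t**alpha).
    """
    _check_common(n_frames, dt)
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if D <= 0:
        raise InvalidParameterError("D must be positive")
    n0 = n_frames - 1
    n_gen = oversample * n0
    target_sd = math.sqrt(2.0 * D * dt ** alpha)
    # phase-averaged variance of a stride increment of W:
    # Var[W(t+delta) - W(t)] = sum_n (1 - cos(gamma^n delta)) / gamma^(n alpha)
    delta = 2.0 * math.pi * oversample / n_gen
    g = _WM_GAMMA ** _WM_N
    wm_sd = math.sqrt(float(np.sum((1.0 - np.cos(g * delta)) / _WM_GAMMA ** (_WM_N * alpha))))
    axes = []
    for _ in range(3):
        phases = rng.uniform(0.0, 2.0 * math.pi, size=_WM_N.size)
        tstar = 2.0 * math.pi * np.arange(n_gen + 1) / n_gen
        w = wm_function(tstar, alpha, phases)
        disp = np.diff(w[::oversample])[:n0]
        disp = disp * (target_sd / wm_sd)
        axes.append(np.concatenate([[0.0], np.cumsum(disp)]))
    pos = np.column_stack(axes)
    return Trajectory3D(traj_id, _times(n_frames, dt), pos, np.full(n_frames, "AD", dtype=object))


# ---------------------------------------------------------------------------
# Confined diffusion
# ---------------------------------------------------------------------------

_CD_SUBSTEPS = 100  # fine sub-steps per frame: ddt = dt / 100
_CD_MAX_ATTEMPTS = 10_000


def simulate_cd(
    n_frames: int,
    dt: float,
    D: float,
    B_param: float,
    rng: np.random.Generator,
    traj_id: str = "cd",
) -> Trajectory3D:
    """Simulate diffusion confined to a sphere of radius r = (D*B_param)^(1/3).

    Brownian sub-steps are taken at ddt = dt/100; any sub-step whose endpoint
    lies farther than r from the start point is rejected and redrawn, so
    every recorded frame satisfies the confinement bound exactly.
    """
    _check_common(n_frames, dt)
    if D <= 0 or B_param <= 0:
        raise InvalidParameterError("D and B_param must be positive")
    r = (D * B_param) ** (1.0 / 3.0)
    r2 = r * r
    ddt = dt / _CD_SUBSTEPS
    sigma = math.sqrt(2.0 * D * ddt)
    n_sub = (n_frames - 1) * _CD_SUBSTEPS
    sub = np.zeros((n_sub + 1, 3))
    cur = np.zeros(3)
    i = 0
    block = 128
    while i < n_sub:
        m = min(block, n_sub - i)
        cand = cur + np.cumsum(rng.normal(0.0, sigma, size=(m, 3)), axis=0)
        d2 = np.einsum("ij,ij->i", cand, cand)
        bad = np.nonzero(d2 > r2)[0]
        if bad.size == 0:
            sub[i + 1 : i + 1 + m] = cand
            cur = cand[-1]
            i += m
            continue
        v = int(bad[0])
        if v > 0:
            sub[i + 1 : i + 1 + v] = cand[:v]
            cur = cand[v - 1]
            i += v
        # redraw the violating sub-step until it lands inside the sphere
        accepted = False
        attempts = 0
        while attempts < _CD_MAX_ATTEMPTS:
            tries = cur + rng.normal(0.0, sigma, size=(64, 3))
            ok = np.nonzero(np.einsum("ij,ij->i", tries, tries) <= r2)[0]
            attempts += 64
            if ok.size:
                cur = tries[int(ok[0])]
                accepted = True
                break
        if not accepted:
            raise SimulationStallError(
                f"confined-diffusion step rejected {_CD_MAX_ATTEMPTS} times "
                f"(r={r:.3g} um, sub-step sd={sigma:.3g} um)"
            )
        i += 1
        sub[i] = cur
    pos = sub[:: _CD_SUBSTEPS]
    return Trajectory3D(traj_id, _times(n_frames, dt), pos, np.full(n_frames, "CD", dtype=object))


# ---------------------------------------------------------------------------
# Mixed motion
# ---------------------------------------------------------------------------

def _simulate_pure(
    label: str, n_frames: int, config: SimulationConfig, rng: np.random.Generator, traj_id: str
) -> Trajectory3D:
    D = float(rng.uniform(*config.D_range))
    if label == "ND":
        return simulate_nd(n_frames, config.dt, D, rng, traj_id)
    if label == "DM":
        return simulate_dm(
            n_frames, config.dt, D, config.coef_range, rng, traj_id,
            angular_noise=config.dm_angular_noise,
        )
    if label == "AD":
        alpha = float(rng.uniform(*config.alpha_range))
        return simulate_ad(n_frames, config.dt, D, alpha, rng, traj_id)
    if label == "CD":
        B = float(rng.uniform(*config.B_range))
        return simulate_cd(n_frames, config.dt, D, B, rng, traj_id)
    raise InvalidParameterError(f"unknown motion label {label!r}")


def simulate_mm(
    n_frames: int,
    dt: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    traj_id: str = "mm",
    segment_labels: Sequence[str] | None = None,
    segment_lengths: Sequence[int] | None = None,
) -> Trajectory3D:
    """Simulate mixed motion: concatenated segments of the four pure regimes.

    Segment lengths are drawn uniformly from ``config.mm_segment_range``;
    segment types are drawn uniformly from {DM, ND, AD, CD} with each new
    segment forced to differ from its predecessor (a mixed trajectory is a
    sequence of transitions between distinct motion types).  Each segment
    continues from the previous endpoint.  Explicit ``segment_labels``/
    ``segment_lengths`` override the random draw.
    """
    _check_common(n_frames, dt)
    lo, hi = config.mm_segment_range
    if segment_lengths is None and (lo < 2 or 2 * lo > n_frames):
        raise InvalidParameterError(
            "mm_segment_range must fit at least two segments into n_frames"
        )
    cfg = config.replace(dt=dt) if config.dt != dt else config

    lengths: list[int] = []
    labels_seq: list[str] = []
    if segment_lengths is not None:
        lengths = list(segment_lengths)
        labels_seq = list(segment_labels)  # type: ignore[arg-type]
    else:
        covered = 0
        while covered < n_frames:
            seg = int(rng.integers(lo, hi + 1))
            seg = min(seg, n_frames - covered)
            lengths.append(seg)
            covered += seg
        k = len(lengths)
        if segment_labels is not None:
            labels_seq = list(segment_labels)[:k]
        else:
            labels_seq = [MOTION_LABELS[int(rng.integers(4))]]
            for _ in range(k - 1):
                others = [c for c in MOTION_LABELS if c != labels_seq[-1]]
                labels_seq.append(others[int(rng.integers(3))])

    pos_parts: list[np.ndarray] = []
    lab_parts: list[np.ndarray] = []
    offset = np.zeros(3)
    first = True
    for seg_label, seg_len in zip(labels_seq, lengths):
        # generate one extra frame and drop it so the segment's first new
        # frame continues the walk instead of duplicating the junction point
        n_gen = seg_len if first else seg_len + 1
        part = _simulate_pure(seg_label, max(n_gen, 2), cfg, rng, traj_id)
        p = part.pos if first else part.pos[1:]
        p = p[:seg_len] + offset
        pos_parts.append(p)
        lab_parts.append(np.full(len(p), seg_label, dtype=object))
        offset = p[-1]
        first = False
    pos = np.vstack(pos_parts)[:n_frames]
    labels = np.concatenate(lab_parts)[:n_frames]
    return Trajectory3D(traj_id, _times(len(pos), dt), pos, labels, motion_class="MM")


# ---------------------------------------------------------------------------
# Dataset generation and MSD
# ---------------------------------------------------------------------------

def _allocate_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n trajectories to classes."""
    items = [(c, mix.get(c, 0.0)) for c in TRAJECTORY_CLASSES]
    raw = {c: n * p for c, p in items}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(items, key=lambda cp: raw[cp[0]] - counts[cp[0]], reverse=True)
    for c, _ in order[:short]:
        counts[c] += 1
    return counts


def generate_dataset(config: SimulationConfig) -> list[Trajectory3D]:
    """Generate the full labeled trajectory set described by ``config``.

    Deterministic under ``config.seed``: trajectory i draws from the i-th
    stream spawned from the seed, so repeated calls are bitwise identical.
    """
    counts = _allocate_counts(config.n_trajectories, config.class_mix)
    root = np.random.SeedSequence(config.seed)
    out: list[Trajectory3D] = []
    idx = 0
    for cls in TRAJECTORY_CLASSES:
        for _ in range(counts[cls]):
            rng = np.random.default_rng(root.spawn(1)[0])
            traj_id = f"{cls.lower()}_{idx:05d}"
            if cls == "MM":
                traj = simulate_mm(config.n_frames, config.dt, config, rng, traj_id)
            else:
                traj = _simulate_pure(cls, config.n_frames, config, rng, traj_id)
            out.append(traj)
            idx += 1
    return out


def empirical_msd(traj: Trajectory3D | np.ndarray, max_lag: int) -> MsdCurve:
    """Time-averaged mean squared displacement over lags 1..max_lag.

    MSD(k) = mean_i ||r_{i+k} - r_i||^2 over all frame pairs k apart.
    """
    pos = traj.pos if isinstance(traj, Trajectory3D) else np.asarray(traj, dtype=float)
    n = len(pos)
    if max_lag >= n:
        raise InvalidParameterError(f"max_lag {max_lag} must be < n_frames {n}")
    if max_lag < 1:
        raise InvalidParameterError("max_lag must be >= 1")
    lags = np.arange(1, max_lag + 1)
    values = np.empty(max_lag)
    for k in lags:
        d = pos[k:] - pos[:-k]
        values[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    return MsdCurve(lags, values)


def theoretical_msd(
    motion_type: str, params: Mapping[str, float], lags: Sequence[int], dt: float
) -> MsdCurve:
    """Closed-form 3D MSD for a pure motion type evaluated at t = lag*dt.

    ND: 6*D*t.  DM: 6*D*t + v^2 t^2.  AD: 6*D*t**alpha.  CD: saturating
    L*(1 - exp(-6*D*t/L)) with plateau L = 6 r^2 / 5, the mean squared
    separation of two uniform points in a ball of radius r.
    """
    lags = np.asarray(lags)
    t = lags * dt
    if motion_type == "ND":
        vals = 6.0 * params["D"] * t
    elif motion_type == "DM":
        vals = 6.0 * params["D"] * t + params["v"] ** 2 * t**2
    elif motion_type == "AD":
        vals = 6.0 * params["D"] * t ** params["alpha"]
    elif motion_type == "CD":
        if "r" in params:
            r = params["r"]
        else:
            r = (params["D"] * params["B_param"]) ** (1.0 / 3.0)
        plateau = 6.0 * r * r / 5.0
        vals = plateau * (1.0 - np.exp(-6.0 * params["D"] * t / plateau))
    else:
        raise InvalidParameterError(f"unknown motion type {motion_type!r}")
    return MsdCurve(lags, vals)
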