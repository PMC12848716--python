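"""Per-window trajectory descriptors for motion classification.

Fourteen features are computed for each fixed-length window: the anomalous
exponent fitted to the window MSD (alpha), angular Gaussianity of turning
angles, gyration-tensor asymmetry, average MSD ratio, efficiency, Katz
fractal dimension, displacement Gaussianity, mean jump length, kurtosis of
positions projected on the dominant gyration axis, maximal and mean maximal
excursion, straightness, trappedness, and lag-1 velocity autocorrelation.

All features are invariant to translation and rigid rotation of the window.
Degenerate windows (e.g. a stationary particle) map to documented finite
fallback values, never NaN/inf.  The same formulas apply to 2D-projected
windows with the dimension-dependent constants (Gaussianity ratio, MSD
prefactor) switched accordingly.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .segment import WindowSample, WindowStack
from .simulate import InvalidParameterError, MsdCurve

__all__ = [
    "FEATURE_NAMES",
    "compute_feature_table",
    "compute_features",
    "fit_alpha",
    "avg_msd_ratio",
    "fractal_dimension",
    "gaussianity",
    "jump_length",
    "kurtosis_projected",
    "asymmetry",
    "excursion_stats",
    "straightness_efficiency",
    "trappedness",
    "velocity_autocorrelation",
    "angular_gaussianity",
]

logger = logging.getLogger(__name__)

#: Canonical feature order; feature tables and models always use this order.
FEATURE_NAMES = (
    "alpha",
    "angular_gaussianity",
    "asymmetry",
    "avg_msd_ratio",
    "efficiency",
    "fractal_dimension",
    "gaussianity",
    "jump_length",
    "kurtosis",
    "maximal_excursion",
    "mean_maximal_excursion",
    "straightness",
    "trappedness",
    "velocity_autocorrelation",
)

DF_MAX = 4.0  # cap on the Katz fractal dimension (log singularity guard)
ASYM_MAX = 10.0  # cap on -ln asymmetry (collinear windows)
TRAP_A = 0.2048  # trappedness exponential coefficients (2D-derived
TRAP_B = 0.25117  # literature fit, retained unchanged in 3D)


def _msd_lag_cap(window: int) -> int:
    # half the window balances lag range against averaging noise
    return max(window // 2, 2)


def _window_msd_moments(P: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged second and fourth displacement moments per window.

    Returns (msd, m4), each of shape (B, max_lag).
    """
    B, W, _ = P.shape
    msd = np.empty((B, max_lag))
    m4 = np.empty((B, max_lag))
    for k in range(1, max_lag + 1):
        d = P[:, k:, :] - P[:, :-k, :]
        r2 = np.einsum("bwd,bwd->bw", d, d)
        msd[:, k - 1] = r2.mean(axis=1)
        m4[:, k - 1] = (r2 * r2).mean(axis=1)
    return msd, m4


def _masked_loglog_slope(y: np.ndarray, x: np.ndarray, min_points: int = 3) -> np.ndarray:
    """Least-squares slope of log(y) vs x per row, ignoring y <= 0 entries."""
    mask = y > 0
    n = mask.sum(axis=1)
    logy = np.where(mask, np.log(np.where(mask, y, 1.0)), 0.0)
    xw = np.where(mask, x[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = xw.sum(axis=1) / n
        ybar = logy.sum(axis=1) / n
        dx = np.where(mask, x[None, :] - xbar[:, None], 0.0)
        sxx = (dx * dx).sum(axis=1)
        sxy = (dx * (logy - ybar[:, None]) * mask).sum(axis=1)
        slope = sxy / sxx
    bad = (n < min_points) | ~np.isfinite(slope)
    return np.where(bad, 0.0, slope)


def _batch_features(P: np.ndarray, dt: float, dim: int) -> dict[str, np.ndarray]:
    """Compute all 14 features for a stack of windows.

    P : (B, W, d) positions with d = dim (2 or 3); dt the frame interval.
    """
    if dim not in (2, 3):
        raise InvalidParameterError("dim must be 2 or 3")
    B, W, d = P.shape
    if W < 3:
        raise InvalidParameterError("windows must have at least 3 frames")
    P = P - P[:, :1, :]  # re-anchor: features are translation invariant
    out: dict[str, np.ndarray] = {}

    V = P[:, 1:, :] - P[:, :-1, :]  # steps (B, W-1, d)
    step2 = np.einsum("bwd,bwd->bw", V, V)
    step_len = np.sqrt(step2)
    L = step_len.sum(axis=1)  # total path length
    n_steps = W - 1

    # --- MSD-derived features -------------------------------------------
    K = _msd_lag_cap(W)
    msd, m4 = _window_msd_moments(P, K)
    lags = np.arange(1, K + 1)
    out["alpha"] = _masked_loglog_slope(msd, np.log(lags * dt))

    ratio_mask = msd[:, 1:] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = msd[:, :-1] / msd[:, 1:] - (lags[:-1] / lags[1:])[None, :]
    nvalid = ratio_mask.sum(axis=1)
    amr = np.where(ratio_mask, ratios, 0.0).sum(axis=1)
    out["avg_msd_ratio"] = np.where(nvalid > 0, amr / np.maximum(nvalid, 1), 0.0)

    kd = 5.0 / 3.0 if dim == 3 else 2.0
    gmask = msd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        g = m4 / (kd * msd * msd) - 1.0
    ng = gmask.sum(axis=1)
    gsum = np.where(gmask, g, 0.0).sum(axis=1)
    out["gaussianity"] = np.where(ng > 0, gsum / np.maximum(ng, 1), 0.0)

    # --- path geometry ---------------------------------------------------
    out["jump_length"] = step_len.mean(axis=1)

    # max pairwise distance via the window Gram matrix
    G = P @ P.transpose(0, 2, 1)  # (B, W, W)
    sq = np.einsum("bii->bi", G)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * G
    dmax = np.sqrt(np.maximum(d2.max(axis=(1, 2)), 0.0))

    logn = math.log(n_steps)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = logn + np.log(dmax / L)
    df = np.full(B, 1.0)
    ok = (dmax > 0) & (L > 0)
    capped = ok & (denom <= logn / DF_MAX)
    mid = ok & ~capped
    df[mid] = logn / denom[mid]
    df[capped] = DF_MAX
    out["fractal_dimension"] = df

    # --- gyration tensor: asymmetry and projected kurtosis ---------------
    mean = P.mean(axis=1, keepdims=True)
    C = P - mean
    Q = np.einsum("bwi,bwj->bij", C, C) / W
    evals, evecs = np.linalg.eigh(Q)  # ascending eigenvalues
    lam_sum = evals.sum(axis=1)
    if d == 3:
        l1, l2, l3 = evals[:, 2], evals[:, 1], evals[:, 0]
        num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    else:
        l1, l2 = evals[:, 1], evals[:, 0]
        num = (l1 - l2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - num / (2.0 * lam_sum * lam_sum)
    asym = np.zeros(B)
    pos_sum = lam_sum > 0
    arg = np.where(pos_sum, arg, 1.0)
    asym[pos_sum & (arg <= math.exp(-ASYM_MAX))] = ASYM_MAX
    inner = pos_sum & (arg > math.exp(-ASYM_MAX))
    asym[inner] = -np.log(arg[inner])
    out["asymmetry"] = np.clip(asym, 0.0, ASYM_MAX)

    vmain = evecs[:, :, -1]  # dominant axis
    proj = np.einsum("bwd,bd->bw", C, vmain)
    m2p = (proj**2).mean(axis=1)
    m4p = (proj**4).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kurt = m4p / (m2p * m2p)
    out["kurtosis"] = np.where(m2p > 0, kurt, 0.0)

    # --- excursions, straightness, trappedness ---------------------------
    dist0 = np.sqrt(np.einsum("bwd,bwd->bw", P, P))  # distance from start
    T = n_steps * dt
    Dhat = msd[:, 0] / (2.0 * d * dt)  # short-lag diffusivity estimate
    norm = np.sqrt(2.0 * d * Dhat * T)
    run_max = np.maximum.accumulate(dist0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        me = run_max[:, -1] / norm
        mme = run_max.mean(axis=1) / norm
    good = norm > 0
    out["maximal_excursion"] = np.where(good, me, 0.0)
    out["mean_maximal_excursion"] = np.where(good, mme, 0.0)

    net = dist0[:, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        st = net / L
        eff = net**2 / (n_steps * step2.sum(axis=1))
    out["straightness"] = np.where(L > 0, st, 0.0)
    out["efficiency"] = np.where(L > 0, eff, 0.0)

    r0 = dmax / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        expo = TRAP_A - TRAP_B * (Dhat * T) / (r0 * r0)
    trap = np.where(r0 > 0, 1.0 - np.exp(np.where(r0 > 0, expo, 0.0)), 1.0)
    out["trappedness"] = np.clip(trap, 0.0, 1.0)

    # --- step correlations ------------------------------------------------
    # normalized as mean(v_i . v_{i+1}) / mean(v_i . v_i) so a perfect
    # alternating zigzag evaluates to exactly -1
    dots = np.einsum("bwd,bwd->bw", V[:, :-1, :], V[:, 1:, :])
    energy = step2.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vac = dots.mean(axis=1) / energy
    out["velocity_autocorrelation"] = np.where(energy > 0, vac, 0.0)

    both = step_len[:, :-1] * step_len[:, 1:]
    valid = both > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(valid, dots / np.where(valid, both, 1.0), 0.0)
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    nang = valid.sum(axis=1)
    t2 = np.where(valid, theta**2, 0.0).sum(axis=1) / np.maximum(nang, 1)
    t4 = np.where(valid, theta**4, 0.0).sum(axis=1) / np.maximum(nang, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ag = t4 / (3.0 * t2 * t2) - 1.0
    out["angular_gaussianity"] = np.where((nang >= 2) & (t2 > 0), ag, 0.0)

    for name, vals in out.items():
        if not np.all(np.isfinite(vals)):  # pragma: no cover - safety net
            raise AssertionError(f"non-finite {name} values produced")
    return out


def compute_feature_table(
    stack: WindowStack, dim: int = 3, chunk: int = 32768
) -> pd.DataFrame:
    """Compute the feature table for a :class:`~sptmotion.segment.WindowStack`.

    Returns a DataFrame with identifier columns (``source_id``, ``start``,
    ``source_class``), the 14 features in canonical order, and the
    ``center_label`` target.  ``dim=2`` drops z and switches the
    dimension-dependent constants.  Work is chunked to bound memory.
    """
    P = stack.pos if dim == 3 else stack.pos[:, :, :2]
    parts = []
    for lo in range(0, len(P), chunk):
        feats = _batch_features(P[lo : lo + chunk], stack.dt, dim)
        parts.append(pd.DataFrame({k: feats[k] for k in FEATURE_NAMES}))
    table = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=list(FEATURE_NAMES))
    )
    table.insert(0, "source_id", stack.source_id)
    table.insert(1, "start", stack.start)
    table.insert(2, "source_class", stack.source_class)
    table["center_label"] = stack.center_label
    table.attrs["dim_tag"] = f"{dim}D"
    return table


def _single(w: WindowSample | np.ndarray, dim: int, dt: float | None) -> dict[str, float]:
    if isinstance(w, WindowSample):
        pos = w.pos
        dt = float(w.t[1] - w.t[0]) if dt is None else dt
    else:
        pos = np.asarray(w, dtype=float)
        if dt is None:
            raise InvalidParameterError("dt required for bare position arrays")
    P = pos[None, :, : dim if dim == 2 else 3]
    feats = _batch_features(P, dt, dim)
    return {k: float(v[0]) for k, v in feats.items()}


def compute_features(
    w: WindowSample | np.ndarray, dim: int = 3, dt: float | None = None
) -> pd.Series:
    """All 14 features of one window as a Series in canonical order."""
    vals = _single(w, dim, dt)
    return pd.Series({k: vals[k] for k in FEATURE_NAMES})


# ---------------------------------------------------------------------------
# Individual feature operations (thin wrappers over the batched kernels)
# ---------------------------------------------------------------------------

def fit_alpha(msd: MsdCurve, dt: float) -> float:
    """Anomalous exponent: slope of log MSD vs log(lag*dt), zeros excluded."""
    y = np.asarray(msd.values, dtype=float)[None, :]
    x = np.log(np.asarray(msd.lags) * dt)
    if (msd.values > 0).sum() < 3:
        logger.warning("fewer than 3 positive MSD values; alpha fallback 0")
        return 0.0
    return float(_masked_loglog_slope(y, x)[0])


def avg_msd_ratio(msd: MsdCurve) -> float:
    """Mean of MSD(n)/MSD(n+1) - n/(n+1) over consecutive lag pairs."""
    v, l = msd.values, np.asarray(msd.lags, dtype=float)
    if len(v) < 2:
        raise InvalidParameterError("need at least 2 lags")
    ok = v[1:] > 0
    if not ok.any():
        return 0.0
    return float(np.mean(v[:-1][ok] / v[1:][ok] - l[:-1][ok] / l[1:][ok]))


def fractal_dimension(w: WindowSample | np.ndarray, dim: int = 3, dt: float = 1.0) -> float:
    """Katz fractal dimension ln(n)/(ln(n)+ln(d/L)), capped at ``DF_MAX``."""
    return _single(w, dim, dt)["fractal_dimension"]


def gaussianity(w: WindowSample | np.ndarray, dim: int = 3, dt: float = 1.0) -> float:
    """Deviation of lagged displacements from the d-dimensional Gaussian
    moment ratio: mean over lags of <r^4>/(K_d <r^2>^2) - 1."""
    return _single(w, dim, dt)["gaussianity"]


def jump_length(w: WindowSample | np.ndarray, dt: float = 1.0) -> float:
    """Mean per-frame Euclidean step length (um)."""
    return _single(w, 3, dt)["jump_length"]


def kurtosis_projected(w: WindowSample | np.ndarray, dim: int = 3, dt: float = 1.0) -> float:
    """Fourth standardized moment of positions projected on the dominant
    gyration-tensor eigenvector (population estimator, not excess)."""
    return _single(w, dim, dt)["kurtosis"]


def asymmetry(w: WindowSample | np.ndarray, dim: int = 3, dt: float = 1.0) -> float:
    """Gyration-tensor anisotropy -ln(1 - spread/(2 trace^2)), capped."""
    return _single(w, dim, dt)["asymmetry"]


def excursion_stats(
    w: WindowSample | np.ndarray, dim: int = 3, dt: float = 1.0
) -> tuple[float, float]:
    """(maximal_excursion, mean_maximal_excursion), normalized by the
    free-diffusion length sqrt(2 d Dhat T)."""
    f = _single(w, dim, dt)
    return f["maximal_excursion"], f["mean_maximal_excursion"]


def straightness_efficiency(
    w: WindowSample | np.ndarray, dt: float = 1.0
) -> tuple[float, float]:
    """(straightness, efficiency): net-over-total path ratios in [0, 1]."""
    f = _single(w, 3, dt)
    return f["straightness"], f["efficiency"]


def trappedness(w: WindowSample | np.ndarray, dt: float | None = None) -> float:
    """Confinement likelihood 1 - exp(0.2048 - 0.25117 Dhat T / r0^2),
    clipped to [0, 1]; a degenerate point window is maximally trapped (1)."""
    return _single(w, 3, dt)["trappedness"]


def velocity_autocorrelation(w: WindowSample | np.ndarray, lag: int = 1, dt: float = 1.0) -> float:
    """Normalized step-vector autocorrelation at the given lag."""
    if isinstance(w, WindowSample):
        pos = w.pos
    else:
        pos = np.asarray(w, dtype=float)
    V = np.diff(pos, axis=0)
    if len(V) < lag + 1:
        raise InvalidParameterError("window too short for requested lag")
    energy = float(np.einsum("ij,ij->", V, V)) / len(V)
    if energy == 0:
        return 0.0
    return float(np.einsum("ij,ij->", V[:-lag], V[lag:]) / (len(V) - lag) / energy)


def angular_gaussianity(w: WindowSample | np.ndarray, dt: float = 1.0) -> float:
    """Gaussianity-type moment ratio of consecutive-step turning angles."""
    return _single(w, 3, dt)["angular_gaussianity"]
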