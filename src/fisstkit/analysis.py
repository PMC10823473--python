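"""Figure-level quantities from trajectories: force-resolved distributions,
free-energy profiles, force-extension curves, and comparison statistics.

All reweighting uses the per-frame observable weights W_F (see the force
tempering module); statistical errors on reweighted means use block averaging
with 5 contiguous blocks, since trajectory frames are autocorrelated.
Zero-probability bins yield *missing* free energies (NaN), never infinities;
comparison operations drop missing bins pairwise and report how many.
The Jensen-Shannon distance convention is fixed: base-2 logarithms and the
square root of the divergence, so the distance lies in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr

from .fisst import FisstState, frame_log_weights
from .trajectory import TrajectoryStore

__all__ = [
    "ReweightedProfile",
    "Profile2D",
    "RmseResult",
    "reweighted_histogram",
    "profile_from_probabilities",
    "force_extension_curve",
    "jensen_shannon_distance",
    "spearman_free_energy",
    "rmse_below_threshold",
    "reweighted_2d_histogram",
    "block_standard_error",
    "kish_effective_sample_size",
    "default_bin_edges",
    "rmse_convergence",
    "moving_average",
]

DEFAULT_N_BINS = 100


@dataclass
class ReweightedProfile:
    """Binned probability and free-energy profile at one target force.

    ``probability`` sums to 1 over the bins; ``free_energy`` is
    -(1/beta) ln p, offset so its minimum is 0, with NaN marking empty bins.
    """

    cv_bin_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    target_force: float
    effective_sample_size: float
    beta: float

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.cv_bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.cv_bin_edges[:-1],
                "bin_right": self.cv_bin_edges[1:],
                "probability": self.probability,
                "free_energy": self.free_energy,
            }
        )


@dataclass
class Profile2D:
    edges_x: np.ndarray
    edges_y: np.ndarray
    probability: np.ndarray  # shape (nx, ny)
    target_force: float
    effective_sample_size: float


@dataclass
class RmseResult:
    """RMSE over comparable bins plus the count of missing-bin sentinels."""

    rmse: float
    n_bins: int
    n_missing: int

    def __float__(self) -> float:
        return self.rmse


def default_bin_edges(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Uniform bins spanning the observed range (the default binning rule)."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def kish_effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w @ w))


def _weights(traj, force, state, weights_mode):
    logw = frame_log_weights(traj, force, state, weights_mode)
    return np.exp(logw - logw.max())


def profile_from_probabilities(edges: np.ndarray, p: np.ndarray, beta: float, force: float,
                               ess: float = math.inf) -> ReweightedProfile:
    """Build a profile from normalized per-bin probabilities."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        a = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)) / beta, np.nan)
    a = a - np.nanmin(a)
    return ReweightedProfile(np.asarray(edges, dtype=float), p, a, force, ess, beta)


def reweighted_histogram(
    traj: TrajectoryStore,
    force: float,
    bin_edges: np.ndarray,
    state: FisstState | None = None,
    weights: str = "stored",
) -> ReweightedProfile:
    """W_F-weighted CV histogram and free-energy profile at a target force.

    On a degenerate single-force grid (or a plain constant-force run analyzed
    at its own force) this reduces to the plain histogram.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1D array")
    w = _weights(traj, force, state, weights)
    counts, _ = np.histogram(traj["Q"], bins=edges, weights=w)
    in_range = counts.sum()
    if in_range <= 0:
        raise ValueError("no frames fall inside the requested bins")
    p = counts / in_range
    beta = state.beta if state is not None else traj.beta
    return profile_from_probabilities(edges, p, beta, force, kish_effective_sample_size(w))


def block_standard_error(values: np.ndarray, weights: np.ndarray | None = None, n_blocks: int = 5) -> float:
    """Standard error of a (weighted) mean from contiguous block averages."""
    v = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(v)
    w = np.asarray(weights, dtype=float)
    if len(v) < n_blocks:
        raise ValueError("fewer frames than blocks")
    means = []
    for chunk_v, chunk_w in zip(np.array_split(v, n_blocks), np.array_split(w, n_blocks)):
        tot = chunk_w.sum()
        means.append((chunk_v * chunk_w).sum() / tot if tot > 0 else np.nan)
    means = np.asarray(means)
    means = means[np.isfinite(means)]
    if len(means) < 2:
        return float("nan")
    return float(np.std(means, ddof=1) / math.sqrt(len(means)))


def force_extension_curve(
    traj: TrajectoryStore,
    forces,
    state: FisstState | None = None,
    weights: str = "stored",
    observable: str = "Q",
) -> pd.DataFrame:
    """Reweighted mean CV versus force: the force-extension curve.

    Columns: force, mean, std, std_over_3 (the 1/3-of-standard-deviation
    error-bar convention also emitted for plotting), block_se.
    """
    rows = []
    q = traj[observable]
    for f in np.atleast_1d(np.asarray(forces, dtype=float)):
        w = _weights(traj, float(f), state, weights)
        mean = float((q * w).sum() / w.sum())
        var = float(((q - mean) ** 2 * w).sum() / w.sum())
        std = math.sqrt(max(var, 0.0))
        rows.append(
            {
                "force": float(f),
                "mean": mean,
                "std": std,
                "std_over_3": std / 3.0,
                "block_se": block_standard_error(q, w),
                "ess": kish_effective_sample_size(w),
            }
        )
    return pd.DataFrame(rows)


def jensen_shannon_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon distance (sqrt of the divergence), in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"distributions on mismatched binnings: {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if not math.isclose(v.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"{name} is not normalized (sums to {v.sum()})")
    return float(jensenshannon(p, q, base=2))


def _common_finite(a: np.ndarray, b: np.ndarray):
    mask = np.isfinite(a) & np.isfinite(b)
    return a[mask], b[mask], mask


def spearman_free_energy(profile_a: ReweightedProfile, profile_b: ReweightedProfile) -> float:
    """Spearman rank correlation between two free-energy profiles.

    Profiles must share bin edges; bins missing (empty) in either profile are
    dropped pairwise.  Ties receive average ranks.
    """
    if not np.array_equal(profile_a.cv_bin_edges, profile_b.cv_bin_edges):
        raise ValueError("profiles are on different binnings")
    fa, fb, _ = _common_finite(profile_a.free_energy, profile_b.free_energy)
    if len(fa) < 3:
        raise ValueError(f"only {len(fa)} common bins; rank correlation undefined")
    rc = spearmanr(fa, fb).statistic
    return float(rc)


def rmse_below_threshold(
    profile_a: ReweightedProfile,
    profile_ref: ReweightedProfile,
    cutoff: float,
) -> RmseResult:
    """RMSE between free-energy profiles over bins where the reference is below cutoff.

    The reference profile's bins define the comparison region.  Each profile is
    already min-offset to zero by construction.  Bins inside the region that
    are missing in either profile are excluded from the RMSE and counted as
    sentinels in ``n_missing``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not np.array_equal(profile_a.cv_bin_edges, profile_ref.cv_bin_edges):
        raise ValueError("profiles are on different binnings")
    ref = profile_ref.free_energy
    region = np.isfinite(ref) & (ref < cutoff)
    if not np.any(region):
        raise ValueError(f"no reference bins below cutoff {cutoff}")
    a = profile_a.free_energy[region]
    r = ref[region]
    ok = np.isfinite(a)
    n_missing = int((~ok).sum())
    if not np.any(ok):
        raise ValueError("no comparable bins below cutoff (all missing in the test profile)")
    err = a[ok] - r[ok]
    return RmseResult(float(np.sqrt(np.mean(err**2))), int(ok.sum()), n_missing)


def reweighted_2d_histogram(
    traj: TrajectoryStore,
    obs_x: str,
    obs_y: str,
    force: float,
    edges_x: np.ndarray,
    edges_y: np.ndarray,
    state: FisstState | None = None,
    weights: str = "stored",
) -> Profile2D:
    """W_F-weighted joint histogram of two recorded observables.

    Marginalizing over either axis reproduces the corresponding 1D reweighted
    histogram exactly (same weights, same normalization).
    """
    for name in (obs_x, obs_y):
        if name not in traj.columns:
            raise KeyError(f"observable {name!r} not recorded; columns: {traj.columns}")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    w = _weights(traj, force, state, weights)
    h, ex, ey = np.histogram2d(traj[obs_x], traj[obs_y], bins=[np.asarray(edges_x), np.asarray(edges_y)], weights=w)
    tot = h.sum()
    if tot <= 0:
        raise ValueError("no frames fall inside the requested bins")
    return Profile2D(np.asarray(edges_x, float), np.asarray(edges_y, float), h / tot, force, kish_effective_sample_size(w))


# ---------------------------------------------------------------------------
# Convergence analysis
# ---------------------------------------------------------------------------

def rmse_convergence(
    traj: TrajectoryStore,
    reference: ReweightedProfile,
    cutoff: float,
    force: float = 0.0,
    n_windows: int = 10,
    state: FisstState | None = None,
    weights: str = "stored",
) -> pd.DataFrame:
    """RMSE of the reweighted profile over growing trajectory prefixes.

    Columns: frames, fraction, rmse, n_missing.  This is the time-windowed
    convergence diagnostic: the curve drops once sampling has reached every
    basin inside the cutoff region.
    """
    n = len(traj)
    rows = []
    for k in range(1, n_windows + 1):
        m = int(round(n * k / n_windows))
        prefix = traj.head(m)
        try:
            prof = reweighted_histogram(prefix, force, reference.cv_bin_edges, state, weights)
            res = rmse_below_threshold(prof, reference, cutoff)
            rows.append({"frames": m, "fraction": k / n_windows, "rmse": res.rmse, "n_missing": res.n_missing})
        except ValueError:
            rows.append({"frames": m, "fraction": k / n_windows, "rmse": np.nan, "n_missing": -1})
    return pd.DataFrame(rows)


def moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving average (shrinking windows at the ends); smooths
    convergence curves before monotonicity checks."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    h = window // 2
    for i in range(len(v)):
        lo, hi = max(0, i - h), min(len(v), i + h + 1)
        out[i] = np.nanmean(v[lo:hi])
    return out
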