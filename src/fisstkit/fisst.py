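"""Infinite-switch simulated tempering in force (FISST).

Instead of pulling at one force, the sampler draws from the force-mixture
density

    p(q)  proportional to  integral_{F_min}^{F_max} dF omega(F) e^{-beta (U(q) - F Q(q))},

the infinite-switch limit of simulated tempering over a ladder of pulling
forces.  The machinery implemented here:

* :class:`ForceGrid` — a uniform discretization of [F_min, F_max] with
  trapezoid quadrature weights; every integral over F is evaluated on it.
* :class:`FisstState` — the force-weight density omega(F) on the grid, the
  running partition-function estimate z(F), sample counts, and the frozen flag.
* ``fbar(Q)`` — the effective pulling force applied during dynamics,
  the exponentially tilted mean of F under omega,
      Fbar(Q) = int dF omega(F) F e^{beta F Q} / int dF omega(F) e^{beta F Q};
  it is the negative CV-derivative of the bias potential
      V(Q) = -(1/beta) log int dF omega(F) e^{beta F Q}.
* weight learning — omega(F) is adapted toward 1/Z_q(F) (so that all forces in
  the range are sampled evenly) with a cumulative mixture-importance estimator:
      zhat(F) = mean over samples of e^{beta F Q_t} / int dF' omega_t(F') e^{beta F' Q_t},
  whose expectation under the mixture is Z_q(F)/C at every stage of adaptation,
  so the learned shape is consistent even while omega is still moving.
* observable weights — per-frame importance weights
      W_F(q) = e^{beta F Q} / int dF' omega(F') e^{beta F' Q}
  turning mixture samples into fixed-force averages for any F on the grid
  (any Q-independent normalization cancels in the weighted-average ratio).

All integrals over F are computed in log space with a max-shift (log-sum-exp
over quadrature nodes), so beta * F * Q far beyond float overflow is safe.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory import TrajectoryStore

__all__ = [
    "ForceGrid",
    "FisstState",
    "FisstBias",
    "fbar",
    "bias_potential",
    "observable_weight",
    "reweighted_average",
    "update_weights",
    "freeze",
    "write_restart",
    "read_restart",
    "RestartError",
]

logger = logging.getLogger(__name__)

_RESTART_FORMAT_VERSION = 1


class RestartError(ValueError):
    """Raised for unreadable, truncated, or version-mismatched restart files."""


@dataclass(frozen=True)
class ForceGrid:
    """Uniform force grid on [f_min, f_max] with trapezoid quadrature weights.

    The quadrature weights sum to (f_max - f_min); the degenerate single-force
    grid (f_min == f_max) carries unit weight so that the mixture collapses to
    a point mass and FISST reduces exactly to a constant-force run.
    """

    f_min: float
    f_max: float
    n_points: int = 121

    def __post_init__(self) -> None:
        if not (math.isfinite(self.f_min) and math.isfinite(self.f_max)):
            raise ValueError("force grid bounds must be finite")
        if self.f_max < self.f_min:
            raise ValueError("f_max must be >= f_min")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.f_max == self.f_min and self.n_points != 1:
            raise ValueError("degenerate grid (f_min == f_max) must have n_points == 1")
        if self.f_max > self.f_min and self.n_points < 2:
            raise ValueError("non-degenerate grid needs n_points >= 2")

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.f_min, self.f_max, self.n_points)

    @property
    def quadrature_weights(self) -> np.ndarray:
        if self.n_points == 1:
            return np.array([1.0])
        h = (self.f_max - self.f_min) / (self.n_points - 1)
        w = np.full(self.n_points, h)
        w[0] = w[-1] = h / 2.0
        return w

    @property
    def degenerate(self) -> bool:
        return self.n_points == 1

    def contains(self, force: float) -> bool:
        return self.f_min <= force <= self.f_max

    def to_dict(self) -> dict:
        return {"f_min": self.f_min, "f_max": self.f_max, "n_points": self.n_points}


class FisstState:
    """omega(F), running z(F) estimate, sample count, and freeze flag.

    ``log_omega`` holds log omega at the grid nodes, normalized so that the
    grid-quadrature integral of omega is exactly 1 after every update.
    ``log_zsum`` accumulates log of the running *sum* of per-sample mixture
    importance ratios (log-space streaming), so zhat = exp(log_zsum)/n_samples.
    """

    def __init__(
        self,
        grid: ForceGrid,
        beta: float,
        update_interval: int = 500,
        log_omega: np.ndarray | None = None,
    ) -> None:
        if not beta > 0 or not math.isfinite(beta):
            raise ValueError("beta must be positive and finite")
        if update_interval < 1:
            raise ValueError("update_interval must be >= 1")
        self.grid = grid
        self.beta = float(beta)
        self.update_interval = int(update_interval)
        self._nodes = grid.nodes
        self._log_w = np.log(grid.quadrature_weights)
        self._version = 0
        if log_omega is None:
            # uniform initial weight density, normalized under the quadrature
            log_omega = np.zeros(grid.n_points)
        self.log_omega = np.asarray(log_omega, dtype=float).copy()
        self._normalize()
        self.log_zsum = np.full(grid.n_points, -np.inf)
        self.n_samples = 0
        self.frozen = False
        self.pending: list[float] = []

    # -- invariants -------------------------------------------------------
    def _normalize(self) -> None:
        if self.grid.degenerate:
            # a normalized single-node density is identically 1 (unit weight);
            # pinning it keeps the single-force reduction exact to the bit
            self.log_omega = np.zeros(1)
            self._tilt = self._log_w + self.log_omega
            self._version += 1
            return
        a = self._log_w + self.log_omega
        m = a.max()
        log_norm = m + math.log(np.exp(a - m).sum())
        # skip sub-roundoff shifts so that normalization is exactly idempotent
        # (restart round-trips must reproduce log_omega bit-for-bit)
        if abs(log_norm) > 1e-14:
            self.log_omega = self.log_omega - log_norm
        if not np.all(np.isfinite(self.log_omega)):
            raise FloatingPointError("non-finite log omega after normalization")
        self._tilt = self._log_w + self.log_omega
        self._version += 1

    @property
    def omega(self) -> np.ndarray:
        """omega(F) at the nodes (integrates to 1 under the grid quadrature)."""
        return np.exp(self.log_omega)

    @property
    def normalization(self) -> float:
        return float(self.grid.quadrature_weights @ self.omega)

    @property
    def log_zhat(self) -> np.ndarray:
        """Log of the running partition-function estimate (up to a constant)."""
        if self.n_samples == 0:
            return np.zeros(self.grid.n_points)
        return self.log_zsum - math.log(self.n_samples)

    # -- core integrals ---------------------------------------------------
    def fbar_and_log_denominator(self, q: float) -> tuple[float, float]:
        """Scalar fast path evaluating Fbar(Q) and the log mixture denominator
        from one shared tilted-weight vector (the dynamics hot loop)."""
        if self.grid.degenerate:
            return self.grid.f_min, self._tilt[0] + self.beta * self.grid.f_min * q
        a = self._tilt + (self.beta * q) * self._nodes
        m = a.max()
        e = np.exp(a - m)
        s = e.sum()
        return float((e @ self._nodes) / s), float(m + math.log(s))

    def log_denominator(self, q) -> np.ndarray | float:
        """log integral dF omega(F) e^{beta F Q}, the mixture denominator."""
        q_arr = np.atleast_1d(np.asarray(q, dtype=float))
        a = self._log_w + self.log_omega + self.beta * np.outer(q_arr, self.grid.nodes)
        m = a.max(axis=1)
        out = m + np.log(np.exp(a - m[:, None]).sum(axis=1))
        return out if np.ndim(q) else float(out[0])

    def copy(self) -> "FisstState":
        new = FisstState(self.grid, self.beta, self.update_interval, self.log_omega)
        new.log_zsum = self.log_zsum.copy()
        new.n_samples = self.n_samples
        new.frozen = self.frozen
        new.pending = list(self.pending)
        return new

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FisstState)
            and self.grid == other.grid
            and self.beta == other.beta
            and self.update_interval == other.update_interval
            and self.frozen == other.frozen
            and self.n_samples == other.n_samples
            and np.array_equal(self.log_omega, other.log_omega)
            and np.array_equal(self.log_zsum, other.log_zsum)
            and self.pending == other.pending
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fbar(q: float, state: FisstState):
    """Effective pulling force Fbar(Q) applied along the CV.

    The tilted mean of F under omega; always inside [f_min, f_max], and
    non-decreasing in Q (its derivative is beta * Var of F under the tilt).
    """
    grid = state.grid
    if grid.degenerate:
        if np.ndim(q):
            return np.full(np.shape(q), grid.f_min)
        return grid.f_min
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if not np.all(np.isfinite(q_arr)):
        raise ValueError("CV value must be finite")
    a = state._log_w + state.log_omega + state.beta * np.outer(q_arr, grid.nodes)
    m = a.max(axis=1)
    e = np.exp(a - m[:, None])
    out = (e @ grid.nodes) / e.sum(axis=1)
    return out if np.ndim(q) else float(out[0])


def bias_potential(q: float, state: FisstState):
    """Bias potential V(Q) = -(1/beta) log int dF omega(F) e^{beta F Q}.

    Its negative CV-derivative equals :func:`fbar`; with normalized omega,
    V(0) = 0.
    """
    if np.ndim(q) == 0 and not math.isfinite(float(q)):
        raise ValueError("CV value must be finite")
    return -(1.0 / state.beta) * state.log_denominator(q)


def observable_weight(q: float, force: float, state: FisstState):
    """Per-frame observable weight W_F(q) for reweighting to a fixed force.

    W_F(q) = e^{beta F Q} / int dF' omega(F') e^{beta F' Q}; strictly positive.
    The target force must lie inside the grid (no extrapolation).
    """
    if not state.grid.contains(force):
        raise ValueError(
            f"target force {force} outside the sampled grid "
            f"[{state.grid.f_min}, {state.grid.f_max}]; reweighting cannot extrapolate"
        )
    logw = state.beta * force * np.asarray(q, dtype=float) - state.log_denominator(q)
    return np.exp(logw)


def log_observable_weight(q, force: float, state: FisstState):
    if not state.grid.contains(force):
        raise ValueError(
            f"target force {force} outside the sampled grid "
            f"[{state.grid.f_min}, {state.grid.f_max}]"
        )
    return state.beta * force * np.asarray(q, dtype=float) - state.log_denominator(q)


def frame_log_weights(traj: TrajectoryStore, force: float, state: FisstState | None = None, weights: str = "stored"):
    """Log observable weights for every frame of a trajectory.

    weights="stored" uses the mixture denominator recorded at sampling time
    (the weights in force when each frame was generated); weights="final"
    recomputes the denominator from the supplied state's current (e.g. frozen)
    omega.  Both conventions are exposed because adaptive runs can be analyzed
    either way.
    """
    q = traj["Q"]
    beta = state.beta if state is not None else traj.beta
    if weights == "stored":
        if "log_denom" not in traj.columns:
            # not a force-tempered run: a constant-force (or unbiased) run is
            # its own fixed-force sample, so weights are uniform — but only at
            # the force it was actually performed at
            run_force = float(traj.meta.get("bias_force", 0.0))
            if force != run_force:
                raise ValueError(
                    f"trajectory was sampled at fixed force {run_force}, not force-tempered; "
                    f"cannot reweight to {force}"
                )
            return np.zeros(len(traj))
        if state is not None and not state.grid.contains(force):
            raise ValueError(f"target force {force} outside the sampled grid")
        return beta * force * q - traj["log_denom"]
    if weights == "final":
        if state is None:
            raise ValueError("weights='final' requires the FisstState")
        return log_observable_weight(q, force, state)
    raise ValueError(f"unknown weights convention {weights!r}")


def reweighted_average(
    traj: TrajectoryStore,
    observable: str,
    force: float,
    state: FisstState | None = None,
    weights: str = "stored",
) -> float:
    """Fixed-force average of a recorded observable from one mixture run.

    Sum_t O_t W_F(q_t) / Sum_t W_F(q_t).  ``observable`` names a trajectory
    column.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if observable not in traj.columns:
        raise KeyError(f"observable {observable!r} not recorded; columns: {traj.columns}")
    logw = frame_log_weights(traj, force, state, weights)
    w = np.exp(logw - logw.max())
    return float((traj[observable] * w).sum() / w.sum())


def update_weights(state: FisstState, samples) -> FisstState:
    """Fold new CV samples into the running z(F) estimate and refresh omega.

    zhat(F) is the cumulative mean over samples of the mixture importance
    ratio e^{beta F Q_t} / int dF' omega_t(F') e^{beta F' Q_t} (accumulated in
    log space), and omega is reset to 1/zhat, renormalized under the grid
    quadrature.  Frozen states are returned unchanged (with a logged warning).
    Returns ``state`` (mutated in place) for convenience.
    """
    if state.frozen:
        logger.warning("update_weights called on a frozen FISST state; ignored")
        return state
    q = np.atleast_1d(np.asarray(samples, dtype=float))
    if q.size == 0:
        raise ValueError("need at least one new sample")
    if not np.all(np.isfinite(q)):
        raise ValueError("CV samples must be finite")
    # log r_t(F) = beta F Q_t - log_denominator(Q_t), batched over t
    logden = state.log_denominator(q)
    log_r = state.beta * np.outer(q, state.grid.nodes) - np.asarray(logden).reshape(-1, 1)
    m = log_r.max(axis=0)
    batch = m + np.log(np.exp(log_r - m).sum(axis=0))
    state.log_zsum = np.logaddexp(state.log_zsum, batch)
    state.n_samples += q.size
    state.log_omega = -(state.log_zsum - math.log(state.n_samples))
    state._normalize()
    return state


def freeze(state: FisstState) -> FisstState:
    """Freeze omega: subsequent updates become no-ops. Idempotent."""
    if not state.frozen:
        logger.info("freezing force weights after %d samples", state.n_samples)
    state.frozen = True
    return state


# ---------------------------------------------------------------------------
# Restart I/O (self-describing structured text)
# ---------------------------------------------------------------------------

def write_restart(state: FisstState, path) -> None:
    """Write a lossless restart file (JSON; float64 round-trips exactly)."""
    payload = {
        "format": "fisstkit-restart",
        "version": _RESTART_FORMAT_VERSION,
        "grid": state.grid.to_dict(),
        "beta": state.beta,
        "update_interval": state.update_interval,
        "log_omega": state.log_omega.tolist(),
        "log_zsum": [None if v == -np.inf else v for v in state.log_zsum.tolist()],
        "n_samples": state.n_samples,
        "frozen": state.frozen,
        "pending": state.pending,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_restart(path) -> FisstState:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise RestartError(f"unreadable FISST restart file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "fisstkit-restart":
        raise RestartError(f"{path} is not a fisstkit restart file")
    if payload.get("version") != _RESTART_FORMAT_VERSION:
        raise RestartError(
            f"restart format version {payload.get('version')} not supported "
            f"(expected {_RESTART_FORMAT_VERSION})"
        )
    try:
        grid = ForceGrid(**payload["grid"])
        state = FisstState(
            grid,
            beta=payload["beta"],
            update_interval=payload["update_interval"],
            log_omega=np.asarray(payload["log_omega"], dtype=float),
        )
        state.log_zsum = np.array(
            [-np.inf if v is None else float(v) for v in payload["log_zsum"]]
        )
        if len(state.log_zsum) != grid.n_points:
            raise KeyError("log_zsum length mismatch")
        state.n_samples = int(payload["n_samples"])
        state.frozen = bool(payload["frozen"])
        state.pending = [float(v) for v in payload["pending"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise RestartError(f"truncated or corrupt FISST restart file {path}: {exc}") from exc
    return state


# ---------------------------------------------------------------------------
# The bias object plugged into the dynamics engine
# ---------------------------------------------------------------------------

class FisstBias:
    """Adaptive FISST bias for the Langevin engine.

    Applies ``fbar(Q)`` along the CV every step, accumulates one CV sample per
    MD step into a buffer, and folds the buffer into the weight estimate every
    ``state.update_interval`` steps (unless frozen).  Energy evaluations (used
    by replica-exchange swap criteria) never touch the statistics; the
    ``energy_calls`` counter exists so that this contract can be asserted.

    ``shared`` mode: several replicas may hold biases referencing one common
    FisstState, pooling their samples into a single z(F) estimator.
    """

    records_log_denom = True

    def __init__(self, state: FisstState, freeze_after: int | None = None) -> None:
        self.state = state
        self.freeze_after = freeze_after
        self.energy_calls = 0
        self.samples_seen = 0
        self._cache = (math.nan, -1, 0.0, 0.0)  # (q, omega version, fbar, log_denom)

    def _eval(self, q: float) -> tuple[float, float]:
        cq, cver, cf, cd = self._cache
        st = self.state
        if q != cq or cver != st._version:
            cf, cd = st.fbar_and_log_denominator(q)
            self._cache = (q, st._version, cf, cd)
        return cf, cd

    def force(self, q: float) -> float:
        return self._eval(q)[0]

    def energy(self, q: float) -> float:
        self.energy_calls += 1
        return -(1.0 / self.state.beta) * self._eval(q)[1]

    def log_denominator(self, q: float) -> float:
        return self._eval(q)[1]

    def on_step(self, q: float) -> None:
        self.samples_seen += 1
        st = self.state
        st.pending.append(q)
        if len(st.pending) >= st.update_interval:
            if not st.frozen:
                update_weights(st, st.pending)
            st.pending = []
        if self.freeze_after is not None and self.samples_seen >= self.freeze_after:
            freeze(st)
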