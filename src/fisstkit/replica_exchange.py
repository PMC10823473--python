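"""Replica ladders: temperature exchange and REST-style solute tempering.

Each replica propagates its own copy of the system under its own Hamiltonian

    H_i = lambda_pp U_pp + kappa_i lambda_pw U_pw + U_ww + V_bias,i(Q)

at inverse temperature beta_i.  In temperature mode the scalings are all 1 and
beta_i follows the geometric ladder T_i = T_base (T_top/T_base)^{i/(N-1)}; in
REST mode every replica runs at beta_0 and lambda_pp = T_0/T_i (with
lambda_pw = sqrt(T_0/T_i) by default) mimics a heated solute.  kappa is the
extra scaling of the non-electrostatic solute-solvent coupling introduced by
the third-generation solute-tempering recipe; the toy systems have a single
non-bonded class, so kappa multiplies the whole pw term (a stated limitation),
and the helper ``rest3_kappa`` implements 1 + 0.005 (m - 3) for m > 3.

Swap attempts between neighbours use the standard two-replica Metropolis rule

    Delta = beta_i [H_i(q_j) - H_i(q_i)] + beta_j [H_j(q_i) - H_j(q_j)],

accepted with probability min(1, e^-Delta); each H includes that replica's own
FISST bias (each replica may carry different weights omega_i).  On acceptance
configurations swap and velocities are rescaled by sqrt(T_new/T_old).  Pairs
alternate deterministically between even (0-1, 2-3, ...) and odd (1-2, 3-4,
...) passes.  FISST statistics accumulate exactly once per MD step, inside the
propagator; the energy evaluations performed while scoring a swap never touch
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import DivergenceError, IntegratorSettings, NullBias, Propagator
from .fisst import FisstBias, FisstState
from .systems import ModelSystem
from .trajectory import TrajectoryStore

__all__ = [
    "LadderConfig",
    "ReplicaScaling",
    "Replica",
    "rest3_kappa",
    "geometric_temperatures",
    "make_temperature_ladder",
    "make_rest_ladder",
    "replica_energy",
    "exchange_attempt",
    "run_ladder",
]


def rest3_kappa(m: int) -> float:
    """Solute-solvent adjustment kappa = 1 + 0.005 (m - 3) for m > 3, else 1."""
    m = int(m)
    return 1.0 + 0.005 * (m - 3) if m > 3 else 1.0


def geometric_temperatures(n_replicas: int, t_base: float, t_top: float) -> np.ndarray:
    """T_i = t_base * (t_top/t_base)^{i/(N-1)}, i = 0..N-1."""
    if n_replicas < 1:
        raise ValueError("need at least one replica")
    if t_top < t_base or t_base <= 0:
        raise ValueError("need 0 < t_base <= t_top")
    if n_replicas == 1:
        return np.array([t_base])
    i = np.arange(n_replicas)
    return t_base * (t_top / t_base) ** (i / (n_replicas - 1))


@dataclass(frozen=True)
class LadderConfig:
    """Replica-ladder shape: size, temperature span, mode, exchange cadence."""

    n_replicas: int
    t_base: float
    t_top: float
    mode: str = "temperature_re"  # temperature_re | rest_scaling | none
    exchange_interval: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("temperature_re", "rest_scaling", "none"):
            raise ValueError(f"unknown ladder mode {self.mode!r}")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.t_top < self.t_base:
            raise ValueError("t_top must be >= t_base")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")

    @property
    def temperatures(self) -> np.ndarray:
        return geometric_temperatures(self.n_replicas, self.t_base, self.t_top)


@dataclass(frozen=True)
class ReplicaScaling:
    """Hamiltonian scaling factors (all 1 in temperature mode)."""

    lambda_pp: float = 1.0
    lambda_pw: float = 1.0
    kappa: float = 1.0

    def tag_scale(self) -> dict[str, float]:
        return {"pp": self.lambda_pp, "pw": self.kappa * self.lambda_pw, "ww": 1.0}


class Replica:
    """One ladder member: a system copy, beta_i, scaling, and its own bias."""

    def __init__(
        self,
        system: ModelSystem,
        settings: IntegratorSettings,
        scaling: ReplicaScaling = ReplicaScaling(),
        bias=None,
        index: int = 0,
    ) -> None:
        self.system = system.copy()
        self.system.tag_scale = scaling.tag_scale()
        self.settings = settings
        self.scaling = scaling
        self.bias = bias if bias is not None else NullBias()
        self.index = index
        self._prop: Propagator | None = None

    @property
    def beta(self) -> float:
        return self.settings.beta

    @property
    def temperature(self) -> float:
        return 1.0 / self.settings.beta

    @property
    def prop(self) -> Propagator:
        if self._prop is None:
            self._prop = Propagator(self.system, self.settings, self.bias)
        return self._prop

    @property
    def step_count(self) -> int:
        return self.prop.step_index


def replica_energy(replica: Replica, positions: np.ndarray) -> float:
    """H_i at the given configuration: scaled tagged energies plus the bias.

    This is the Hamiltonian entering the exchange criterion, so it includes
    the replica's own FISST bias potential at its own current weights.
    """
    tagged = replica.system.tagged_energies(positions)
    s = replica.system.tag_scale
    u = s["pp"] * tagged["pp"] + s["pw"] * tagged["pw"] + s["ww"] * tagged["ww"]
    q = replica.system.cv(positions)
    return u + replica.bias.energy(q)


def exchange_attempt(replica_i: Replica, replica_j: Replica, rng: np.random.Generator) -> bool:
    """Metropolis swap attempt between two replicas; returns acceptance.

    Delta = beta_i [H_i(q_j) - H_i(q_i)] + beta_j [H_j(q_i) - H_j(q_j)].
    On acceptance positions (and velocities, rescaled by sqrt(T_new/T_old))
    swap between the replicas.  A uniform random number is drawn for every
    attempt so the decision stream is reproducible regardless of outcomes.
    """
    if replica_i.step_count != replica_j.step_count:
        raise RuntimeError(
            f"replicas {replica_i.index} and {replica_j.index} are at different "
            f"step counts ({replica_i.step_count} vs {replica_j.step_count})"
        )
    pi, pj = replica_i.prop, replica_j.prop
    hi_i = replica_energy(replica_i, pi.x)
    hi_j = replica_energy(replica_i, pj.x)
    hj_i = replica_energy(replica_j, pi.x)
    hj_j = replica_energy(replica_j, pj.x)
    delta = replica_i.beta * (hi_j - hi_i) + replica_j.beta * (hj_i - hj_j)
    u = rng.random()
    accepted = delta <= 0.0 or u < math.exp(-delta)
    if accepted:
        scale_ij = math.sqrt(replica_i.temperature / replica_j.temperature)
        xi, vi = pi.x, pi.v
        pi.x, pi.v = pj.x, pj.v * scale_ij
        pj.x, pj.v = xi, vi / scale_ij
        for p in (pi, pj):
            p.q = p.system.cv(p.x)
            p._gradq = p.system.cv_gradient(p.x)
            p._f = p._total_force(p.x, p.q, p._gradq)
    replica_i._last_delta = delta
    return accepted


def run_ladder(
    replicas: list[Replica],
    n_steps: int,
    exchange_interval: int = 100,
    exchange_seed: int = 0,
    exchange_enabled: bool = True,
) -> tuple[list[TrajectoryStore], pd.DataFrame]:
    """Propagate all replicas with alternating even/odd neighbour swaps.

    Returns per-replica trajectories (index 0 = bottom replica, the one whose
    statistics analyses read by default) and the exchange log
    (attempt, step, pair, delta, accepted).  A single replica reduces exactly
    to a plain run with the same seed.  Any replica whose energy diverges
    aborts the ladder with its index in the message.
    """
    if not replicas:
        raise ValueError("need at least one replica")
    rng = np.random.default_rng(exchange_seed)
    log: list[tuple] = []
    attempt = 0
    parity = 0
    for r in replicas:
        try:
            r.prop  # instantiate propagators (and velocity draws) in ladder order
        except DivergenceError as exc:
            raise DivergenceError(f"replica {r.index}: {exc}") from exc
    step = 0
    while step < n_steps:
        n_chunk = min(exchange_interval, n_steps - step)
        for r in replicas:
            try:
                p = r.prop
                rec = r.settings.record_interval
                for _ in range(n_chunk):
                    p.step()
                    if p.step_index % rec == 0:
                        p.record()
            except DivergenceError as exc:
                raise DivergenceError(f"replica {r.index}: {exc}") from exc
        step += n_chunk
        if exchange_enabled and len(replicas) > 1:
            pairs = [(k, k + 1) for k in range(parity, len(replicas) - 1, 2)]
            for i, j in pairs:
                acc = exchange_attempt(replicas[i], replicas[j], rng)
                log.append((attempt, step, i, j, replicas[i]._last_delta, bool(acc)))
                attempt += 1
            parity = 1 - parity
    trajs = [r.prop.trajectory() for r in replicas]
    for r, t in zip(replicas, trajs):
        t.meta.update(
            replica_index=r.index,
            temperature=r.temperature,
            lambda_pp=r.scaling.lambda_pp,
            lambda_pw=r.scaling.lambda_pw,
            kappa=r.scaling.kappa,
        )
    exlog = pd.DataFrame(log, columns=["attempt", "step", "i", "j", "delta", "accepted"])
    return trajs, exlog


# ---------------------------------------------------------------------------
# Ladder builders
# ---------------------------------------------------------------------------

def _replica_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_temperature_ladder(
    system: ModelSystem,
    ladder: LadderConfig,
    settings: IntegratorSettings,
    fisst_factory=None,
) -> list[Replica]:
    """Replicas at the geometric temperature ladder, unscaled Hamiltonians.

    ``fisst_factory(i, beta_i) -> FisstBias | None`` may attach a per-replica
    FISST bias; each replica's bias uses its own beta_i in every tilt factor
    (the bias is part of that replica's Hamiltonian).
    """
    temps = ladder.temperatures
    seeds = _replica_seeds(settings.seed, len(temps))
    reps = []
    for i, t in enumerate(temps):
        s = replace(settings, beta=1.0 / t, seed=seeds[i])
        bias = fisst_factory(i, 1.0 / t) if fisst_factory is not None else None
        reps.append(Replica(system, s, ReplicaScaling(), bias, index=i))
    return reps


def make_rest_ladder(
    system: ModelSystem,
    ladder: LadderConfig,
    settings: IntegratorSettings,
    kappas: list[float] | None = None,
    fisst_factory=None,
) -> list[Replica]:
    """Solute-tempering replicas: all at beta_0, lambda_pp = T_0/T_i.

    lambda_pw defaults to sqrt(T_0/T_i); ``kappas`` (one per replica) defaults
    to 1 for every replica (second-generation behaviour).
    """
    temps = ladder.temperatures
    t0 = ladder.t_base
    seeds = _replica_seeds(settings.seed, len(temps))
    reps = []
    for i, t in enumerate(temps):
        lam = t0 / t
        kap = 1.0 if kappas is None else float(kappas[i])
        s = replace(settings, beta=1.0 / t0, seed=seeds[i])
        bias = fisst_factory(i, 1.0 / t0) if fisst_factory is not None else None
        scaling = ReplicaScaling(lambda_pp=lam, lambda_pw=math.sqrt(lam), kappa=kap)
        reps.append(Replica(system, s, scaling, bias, index=i))
    return reps


def pool_statistics(replicas: list[Replica]) -> FisstState:
    """Switch the replicas' FISST biases to one shared (pooled) state.

    All replicas must carry a FISST bias on the same grid with the same beta
    convention.  Returns the shared state (taken from the bottom replica).
    In the default per-replica mode each replica learns its own omega.
    """
    biases = [r.bias for r in replicas]
    if not all(isinstance(b, FisstBias) for b in biases):
        raise ValueError("every replica needs a FISST bias to pool statistics")
    ref = biases[0].state
    for b in biases[1:]:
        if b.state.grid != ref.grid:
            raise ValueError("cannot pool FISST statistics across different force grids")
        if b.state.beta != ref.beta:
            raise ValueError("cannot pool FISST statistics across different beta conventions")
    for b in biases[1:]:
        b.state = ref
    return ref
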