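"""Independent quadrature references for 1D CV-space fixtures.

These brute-force oracles evaluate Boltzmann and force-mixture expectations by
dense trapezoid quadrature over the CV, entirely independently of the sampling
path, and serve as ground truth in the test suite.  They are 1D only: the
polymer fixture is validated statistically by direct sampling instead, since
quadrature in 3N dimensions is out of reach.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .fisst import FisstState
from .systems import ModelSystem

__all__ = ["QuadratureOracle", "oracle_for_system"]


class QuadratureOracle:
    """High-resolution quadrature over a 1D potential U(Q).

    Parameters
    ----------
    potential : callable U(Q) accepting an array of CV values.
    beta : inverse temperature.
    q_grid : dense CV grid; should be at least 10x finer than any sampler
        histogram and wide enough that the Boltzmann tails are negligible
        (checked: relative tail mass < 1e-10 at every requested force).
    """

    def __init__(self, potential: Callable[[np.ndarray], np.ndarray], beta: float, q_grid: np.ndarray) -> None:
        if beta <= 0:
            raise ValueError("beta must be positive")
        self.potential = potential
        self.beta = float(beta)
        self.q = np.asarray(q_grid, dtype=float)
        if self.q.ndim != 1 or self.q.size < 10:
            raise ValueError("q_grid must be a 1D grid with at least 10 points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q_grid must be strictly increasing")
        self.u = np.asarray(potential(self.q), dtype=float)
        # trapezoid weights on a possibly non-uniform grid
        dq = np.diff(self.q)
        w = np.zeros_like(self.q)
        w[:-1] += dq / 2
        w[1:] += dq / 2
        self._log_w = np.log(w)

    # -- internals --------------------------------------------------------
    def _log_boltzmann(self, force: float) -> np.ndarray:
        return self._log_w - self.beta * self.u + self.beta * force * self.q

    def _check_tails(self, log_terms: np.ndarray) -> None:
        total = logsumexp(log_terms)
        edge = np.logaddexp(log_terms[0], log_terms[-1])
        if edge - total > math.log(1e-10):
            raise ValueError(
                "Boltzmann density does not vanish at the edges of the oracle "
                "grid (tail mass above 1e-10); widen q_grid"
            )

    # -- operations -------------------------------------------------------
    def log_partition(self, force: float) -> float:
        lt = self._log_boltzmann(force)
        self._check_tails(lt)
        return float(logsumexp(lt))

    def partition_ratio(self, force: float) -> float:
        """log Z_q(F) - log Z_q(0)."""
        return self.log_partition(force) - self.log_partition(0.0)

    def boltzmann_expectation(self, observable: Callable[[np.ndarray], np.ndarray], force: float = 0.0) -> float:
        """< O(Q) > under density proportional to e^{-beta (U - F Q)}."""
        lt = self._log_boltzmann(force)
        self._check_tails(lt)
        w = np.exp(lt - lt.max())
        return float((np.asarray(observable(self.q)) * w).sum() / w.sum())

    def density(self, force: float = 0.0) -> np.ndarray:
        """Normalized Boltzmann density on the oracle grid at constant force."""
        lt = self._log_boltzmann(force) - self._log_w
        self._check_tails(lt + self._log_w)
        p = np.exp(lt - lt.max())
        norm = np.exp(self._log_w) @ p
        return p / norm

    def bin_probabilities(self, bin_edges: np.ndarray, force: float = 0.0) -> np.ndarray:
        """Exact per-bin probabilities of the constant-force density."""
        return self._bin_from_logdensity(self._log_boltzmann(force), bin_edges)

    def mixture_density(self, state: FisstState) -> np.ndarray:
        """Normalized FISST mixture density int dF omega(F) e^{-beta(U - F Q)} / C."""
        ld = self._mixture_logdensity(state)
        p = np.exp(ld - ld.max())
        norm = np.exp(self._log_w) @ p
        return p / norm

    def mixture_bin_probabilities(self, state: FisstState, bin_edges: np.ndarray) -> np.ndarray:
        return self._bin_from_logdensity(self._mixture_logdensity(state) + self._log_w, bin_edges)

    def pmf(self, bin_edges: np.ndarray, force: float = 0.0):
        """Exact binned free-energy profile (min offset to zero) at a force."""
        from .analysis import profile_from_probabilities

        p = self.bin_probabilities(bin_edges, force)
        return profile_from_probabilities(np.asarray(bin_edges, dtype=float), p, self.beta, force)

    # -- helpers ----------------------------------------------------------
    def _mixture_logdensity(self, state: FisstState) -> np.ndarray:
        if state.beta != self.beta:
            raise ValueError("oracle and FISST state use different beta")
        return -self.beta * self.u + np.asarray(state.log_denominator(self.q))

    def _bin_from_logdensity(self, log_terms: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
        self._check_tails(log_terms)
        edges = np.asarray(bin_edges, dtype=float)
        mass = np.exp(log_terms - log_terms.max())
        idx = np.searchsorted(edges, self.q)
        p = np.zeros(len(edges) - 1)
        for b in range(len(p)):
            p[b] = mass[idx == b + 1].sum()
        total = p.sum()
        if total <= 0:
            raise ValueError("bin edges do not cover the oracle density")
        return p / total

    def refine_check(self, observable: Callable, force: float = 0.0) -> float:
        """Self-convergence: relative change of an expectation when the grid is doubled."""
        fine = QuadratureOracle(self.potential, self.beta, _double_grid(self.q))
        a = self.boltzmann_expectation(observable, force)
        b = fine.boltzmann_expectation(observable, force)
        denom = max(abs(a), abs(b), 1e-12)
        return abs(a - b) / denom


def _double_grid(q: np.ndarray) -> np.ndarray:
    mid = 0.5 * (q[:-1] + q[1:])
    out = np.empty(q.size + mid.size)
    out[0::2] = q
    out[1::2] = mid
    return out


def oracle_for_system(system: ModelSystem, beta: float, q_grid: np.ndarray) -> QuadratureOracle:
    """Build an oracle for a 1D (single-coordinate, signed-CV) model system."""
    if system.n_particles != 1 or system.n_dim != 1:
        raise ValueError("quadrature oracles are available for 1D systems only")

    def u(q: np.ndarray) -> np.ndarray:
        qa = np.atleast_1d(q)
        return np.array([system.potential(np.array([[v]])) for v in qa])

    return QuadratureOracle(u, beta, q_grid)
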