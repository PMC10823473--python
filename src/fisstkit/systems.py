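"""Toy model systems: potentials, group-tagged energy terms, and collective variables.

Three fixtures are provided, all in reduced units (k_B = 1, temperature in energy
units, lengths dimensionless):

* a single-coordinate harmonic well with a signed CV, whose statistics under a
  constant pulling force are available in closed form (Gaussian tilting);
* a symmetric 1D double well (quartic, or a flat-top "plateau" variant with stiff
  wells and a broad barrier) standing in for a two-basin conformational landscape;
* a 3D bead-spring polymer ("solute") with optional repulsive solvent particles in
  a periodic box, whose end-to-end distance plays the role of the pulling CV and
  whose energy terms carry the solute-solute (pp) / solute-solvent (pw) /
  solvent-solvent (ww) decomposition used by solute-tempering ladders.

Every energy term is tagged with exactly one of {pp, pw, ww}; the total potential
is the tag-weighted sum, which is what Hamiltonian-scaling replicas rescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EnergyTerm",
    "CvSpec",
    "ModelSystem",
    "make_harmonic_cv_system",
    "make_double_well_system",
    "make_polymer_system",
    "write_xyz",
    "read_xyz",
]

GROUP_TAGS = ("pp", "pw", "ww")


@dataclass
class EnergyTerm:
    """One tagged contribution to the potential.

    ``energy(x)`` returns a scalar, ``force(x)`` the negative gradient with the
    same shape as the position array.
    """

    name: str
    tag: str
    energy: Callable[[np.ndarray], float]
    force: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if self.tag not in GROUP_TAGS:
            raise ValueError(f"energy term {self.name!r}: tag must be one of {GROUP_TAGS}, got {self.tag!r}")


@dataclass
class CvSpec:
    """Collective variable metadata.

    kind
        ``end_end_distance`` (non-negative distance between two tagged particles),
        ``signed_coordinate`` (unbounded 1D coordinate) or ``custom``.
    endpoint_indices
        particle indices used by distance CVs.
    """

    kind: str
    endpoint_indices: tuple[int, int] | None = None
    name: str = "Q"


class ModelSystem:
    """Positions, masses, group labels, tagged energy terms, and a CV.

    Parameters
    ----------
    positions : (n, d) array of initial coordinates.
    masses : per-particle masses (broadcast to n).
    group_labels : per-particle tags, each ``"solute"`` or ``"solvent"``.
    terms : tagged :class:`EnergyTerm` objects; the potential is their sum.
    cv_spec : the collective variable definition.
    cv_value / cv_gradient : callables evaluating Q(x) and its gradient.
    box : periodic box length (minimum image applied inside pair terms), or None.
    """

    def __init__(
        self,
        positions: np.ndarray,
        masses: np.ndarray,
        group_labels: Sequence[str],
        terms: Sequence[EnergyTerm],
        cv_spec: CvSpec,
        cv_value: Callable[[np.ndarray], float],
        cv_gradient: Callable[[np.ndarray], np.ndarray],
        box: float | None = None,
        observables: Callable[[np.ndarray], dict] | None = None,
        name: str = "system",
    ) -> None:
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2:
            raise ValueError("positions must have shape (n_particles, n_dim)")
        n = positions.shape[0]
        labels = tuple(group_labels)
        if len(labels) != n:
            raise ValueError("need exactly one group label per particle")
        for lab in labels:
            if lab not in ("solute", "solvent"):
                raise ValueError(f"unknown group label {lab!r}")
        self.positions = positions
        self.masses = np.broadcast_to(np.asarray(masses, dtype=float), (n,)).copy()
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        self.group_labels = labels
        self.terms = list(terms)
        self.cv_spec = cv_spec
        self._cv_value = cv_value
        self._cv_gradient = cv_gradient
        self.box = box
        self._observables = observables
        self.name = name
        # Hamiltonian scaling factors applied per tag (identity by default).
        # Solute-tempering replicas override these; see replica_exchange.
        self.tag_scale: dict[str, float] = {"pp": 1.0, "pw": 1.0, "ww": 1.0}

    # -- energies ---------------------------------------------------------
    def tagged_energies(self, x: np.ndarray) -> dict[str, float]:
        """Unscaled energy per group tag (U_pp, U_pw, U_ww)."""
        out = {"pp": 0.0, "pw": 0.0, "ww": 0.0}
        for t in self.terms:
            out[t.tag] += t.energy(x)
        return out

    def potential(self, x: np.ndarray) -> float:
        """Total potential with the current tag scaling applied."""
        s = self.tag_scale
        u = 0.0
        for t in self.terms:
            u += s[t.tag] * t.energy(x)
        return u

    def forces(self, x: np.ndarray) -> np.ndarray:
        s = self.tag_scale
        f = np.zeros_like(x)
        for t in self.terms:
            f += s[t.tag] * t.force(x)
        return f

    # -- collective variable ---------------------------------------------
    def cv(self, x: np.ndarray) -> float:
        return self._cv_value(x)

    def cv_gradient(self, x: np.ndarray) -> np.ndarray:
        return self._cv_gradient(x)

    def observables(self, x: np.ndarray) -> dict:
        if self._observables is None:
            return {}
        return self._observables(x)

    def copy(self) -> "ModelSystem":
        import copy as _copy

        new = _copy.copy(self)
        new.positions = self.positions.copy()
        new.tag_scale = dict(self.tag_scale)
        return new

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dim(self) -> int:
        return self.positions.shape[1]


# ---------------------------------------------------------------------------
# 1D fixtures
# ---------------------------------------------------------------------------

def _signed_coordinate_cv() -> tuple[CvSpec, Callable, Callable]:
    spec = CvSpec(kind="signed_coordinate", name="Q")

    def value(x: np.ndarray) -> float:
        return float(x[0, 0])

    def gradient(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        g[0, 0] = 1.0
        return g

    return spec, value, gradient


def make_harmonic_cv_system(stiffness: float = 1.0, center: float = 0.0) -> ModelSystem:
    """Single coordinate in a harmonic well, U = k (Q - mu)^2 / 2, signed CV Q.

    Under inverse temperature beta and constant pulling force F the closed forms
    are Gaussian: <Q>_F = mu + F/k, Var(Q) = 1/(beta k) and
    log Z(F) - log Z(0) = beta F mu + beta F^2 / (2 k); the test oracles rely on
    these identities.
    """
    k = float(stiffness)
    mu = float(center)
    if not k > 0:
        raise ValueError(f"stiffness must be positive, got {k}")

    def energy(x: np.ndarray) -> float:
        dq = x[0, 0] - mu
        return 0.5 * k * dq * dq

    def force(x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        f[0, 0] = -k * (x[0, 0] - mu)
        return f

    spec, value, gradient = _signed_coordinate_cv()
    term = EnergyTerm("harmonic_well", "pp", energy, force)
    sys = ModelSystem(
        positions=np.array([[mu]]),
        masses=1.0,
        group_labels=["solute"],
        terms=[term],
        cv_spec=spec,
        cv_value=value,
        cv_gradient=gradient,
        name="harmonic",
    )
    sys.stiffness = k
    sys.center = mu
    return sys


def make_double_well_system(
    barrier: float = 8.0,
    well_separation: float = 2.0,
    form: str = "quartic",
    wall_sharpness: float = 0.04,
) -> ModelSystem:
    """Symmetric 1D double well with minima at +-well_separation/2 and barrier height ``barrier``.

    Two functional forms are available (a config choice; both are symmetric,
    U(Q) = U(-Q), with U = 0 at the minima and U(0) = barrier):

    ``quartic``
        U = b ((Q/a)^2 - 1)^2 — the textbook landscape; well and barrier
        curvatures are tied together (omega_well^2 = 8 b / a^2).
    ``plateau``
        U = b tanh( ((Q/a)^2 - 1)^2 / c ) with c = ``wall_sharpness`` — stiff
        narrow wells (omega_well^2 = 8 b / (c a^2)) separated by a broad flat
        barrier.  This separates the in-well relaxation time from the barrier
        attempt frequency, which is what makes a desk-scale run both converge
        within each basin and stay kinetically trapped between them.
    """
    b = float(barrier)
    a = float(well_separation) / 2.0
    if not b > 0:
        raise ValueError(f"barrier must be positive, got {b}")
    if not a > 0:
        raise ValueError(f"well_separation must be positive, got {well_separation}")

    if form == "quartic":

        def energy(x: np.ndarray) -> float:
            s = (x[0, 0] / a) ** 2 - 1.0
            return b * s * s

        def force(x: np.ndarray) -> np.ndarray:
            q = x[0, 0]
            s = (q / a) ** 2 - 1.0
            f = np.zeros_like(x)
            f[0, 0] = -4.0 * b * s * q / (a * a)
            return f

    elif form == "plateau":
        # s = (Q/a)^2 - 1 vanishes at the wells; inside (s < 0) the saturating
        # tanh gives a flat barrier of height b, outside (s > 0) a b*s^2 wall
        # confines the coordinate (the tanh alone would plateau outward too,
        # leaving an improper density).
        c = float(wall_sharpness)
        if not c > 0:
            raise ValueError("wall_sharpness must be positive")

        def energy(x: np.ndarray) -> float:
            s = (x[0, 0] / a) ** 2 - 1.0
            u = b * math.tanh(s * s / c)
            if s > 0.0:
                u += b * s * s
            return u

        def force(x: np.ndarray) -> np.ndarray:
            q = x[0, 0]
            s = (q / a) ** 2 - 1.0
            t = math.tanh(s * s / c)
            # dU/dq = b sech^2(s^2/c) * (2 s / c) * (2 q / a^2) [+ wall term]
            du = b * (1.0 - t * t) * 4.0 * s * q / (c * a * a)
            if s > 0.0:
                du += 4.0 * b * s * q / (a * a)
            f = np.zeros_like(x)
            f[0, 0] = -du
            return f

    else:
        raise ValueError(f"unknown double-well form {form!r}")

    spec, value, gradient = _signed_coordinate_cv()
    term = EnergyTerm(f"double_well_{form}", "pp", energy, force)
    sys = ModelSystem(
        positions=np.array([[-a]]),
        masses=1.0,
        group_labels=["solute"],
        terms=[term],
        cv_spec=spec,
        cv_value=value,
        cv_gradient=gradient,
        name=f"double_well_{form}",
    )
    sys.barrier = b
    sys.well_position = a
    return sys


# ---------------------------------------------------------------------------
# 3D bead-spring polymer with solvent
# ---------------------------------------------------------------------------

def _min_image(dr: np.ndarray, box: float | None) -> np.ndarray:
    if box is None:
        return dr
    return dr - box * np.round(dr / box)


def _wca_pair(dr2: np.ndarray, eps: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """WCA (purely repulsive Lennard-Jones) energy and -dU/dr2 per pair."""
    rc2 = sigma * sigma * 2.0 ** (1.0 / 3.0)
    inside = (dr2 < rc2) & (dr2 > 0)
    e = np.zeros_like(dr2)
    g = np.zeros_like(dr2)  # dU/d(r^2)
    if np.any(inside):
        s2 = sigma * sigma / dr2[inside]
        s6 = s2 * s2 * s2
        e[inside] = 4.0 * eps * (s6 * s6 - s6) + eps
        g[inside] = 4.0 * eps * (-6.0 * s6 * s6 + 3.0 * s6) / dr2[inside]
    return e, g


def make_polymer_system(
    n_beads: int = 8,
    bond_k: float = 10.0,
    excluded_volume_eps: float = 1.0,
    n_solvent: int = 0,
    rest_length: float = 1.0,
    wca_sigma: float = 1.0,
    box: float | None = None,
    seed: int = 0,
) -> ModelSystem:
    """3D bead-spring chain (solute) plus WCA solvent particles in a periodic box.

    Harmonic bonds U = k (r - r0)^2 / 2 and solute-solute WCA repulsion are tagged
    ``pp``; solute-solvent WCA is ``pw``; solvent-solvent WCA is ``ww``.  The CV
    is the distance between the first and last bead.  With
    ``excluded_volume_eps = 0`` and ``rest_length = 0`` the chain is ideal and
    <d_end^2> = 3 (n_beads - 1) / (beta bond_k) exactly.
    """
    n_beads = int(n_beads)
    if n_beads < 2:
        raise ValueError(f"n_beads must be >= 2, got {n_beads}")
    if bond_k <= 0:
        raise ValueError("bond_k must be positive")
    n_solvent = int(n_solvent)
    n = n_beads + n_solvent
    if box is None:
        box = max(2.0 * wca_sigma, 1.3 * (n ** (1.0 / 3.0)) * wca_sigma, 0.8 * n_beads * max(rest_length, 1.0))
    rng = np.random.default_rng(seed)

    pos = np.zeros((n, 3))
    spacing = rest_length if rest_length > 0 else wca_sigma
    pos[:n_beads, 0] = spacing * np.arange(n_beads)
    pos[:n_beads, 0] -= pos[:n_beads, 0].mean()
    if n_solvent:
        # rejection-sample solvent positions clear of existing particles so the
        # repulsive cores never start overlapped (which would blow up forces)
        min_d2 = (0.95 * wca_sigma) ** 2
        placed = n_beads
        tries = 0
        while placed < n and tries < 20000:
            cand = rng.uniform(-box / 2, box / 2, size=3)
            dr = _min_image(pos[:placed] - cand, box)
            if np.min(np.einsum("ij,ij->i", dr, dr)) > min_d2:
                pos[placed] = cand
                placed += 1
            tries += 1
        if placed < n:
            raise ValueError(
                f"could not place {n_solvent} solvent particles in box {box:.3g}; increase box"
            )

    labels = ["solute"] * n_beads + ["solvent"] * n_solvent
    bead_idx = np.arange(n_beads)
    solv_idx = np.arange(n_beads, n)

    terms: list[EnergyTerm] = []

    # -- bonds (pp) --
    def bond_energy(x: np.ndarray) -> float:
        d = x[1:n_beads] - x[: n_beads - 1]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        dr = r - rest_length
        return 0.5 * bond_k * float(dr @ dr)

    def bond_force(x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        d = x[1:n_beads] - x[: n_beads - 1]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        r = np.where(r > 1e-12, r, 1e-12)
        coef = bond_k * (r - rest_length) / r
        pair_f = coef[:, None] * d  # force on the earlier bead of the pair
        np.add.at(f, bead_idx[:-1], pair_f)
        np.add.at(f, bead_idx[1:], -pair_f)
        return f

    terms.append(EnergyTerm("bonds", "pp", bond_energy, bond_force))

    def _pair_term(idx_a, idx_b, tag, name, same_group, mi_box):
        """WCA term between groups.

        ``mi_box`` is the minimum-image box, or None for direct distances
        (intramolecular solute pairs: the chain is kept whole/unwrapped).
        """

        def energy(x: np.ndarray) -> float:
            if same_group:
                xa = x[idx_a]
                dr = _min_image(xa[:, None, :] - xa[None, :, :], mi_box)
                dr2 = np.einsum("ijk,ijk->ij", dr, dr)
                iu = np.triu_indices(len(idx_a), k=1)
                e, _ = _wca_pair(dr2[iu], excluded_volume_eps, wca_sigma)
            else:
                dr = _min_image(x[idx_a][:, None, :] - x[idx_b][None, :, :], mi_box)
                dr2 = np.einsum("ijk,ijk->ij", dr, dr).ravel()
                e, _ = _wca_pair(dr2, excluded_volume_eps, wca_sigma)
            return float(e.sum())

        def force(x: np.ndarray) -> np.ndarray:
            f = np.zeros_like(x)
            if same_group:
                xa = x[idx_a]
                dr = _min_image(xa[:, None, :] - xa[None, :, :], mi_box)
                dr2 = np.einsum("ijk,ijk->ij", dr, dr)
                np.fill_diagonal(dr2, np.inf)
                _, g = _wca_pair(dr2.ravel(), excluded_volume_eps, wca_sigma)
                g = g.reshape(dr2.shape)
                # F_i = -sum_j dU/dr2 * 2 dr_ij
                fa = -2.0 * np.einsum("ij,ijk->ik", g, dr)
                np.add.at(f, idx_a, fa)
            else:
                dr = _min_image(x[idx_a][:, None, :] - x[idx_b][None, :, :], mi_box)
                dr2 = np.einsum("ijk,ijk->ij", dr, dr)
                _, g = _wca_pair(dr2.ravel(), excluded_volume_eps, wca_sigma)
                g = g.reshape(dr2.shape)
                fa = -2.0 * np.einsum("ij,ijk->ik", g, dr)
                fb = 2.0 * np.einsum("ij,ijk->jk", g, dr)
                np.add.at(f, idx_a, fa)
                np.add.at(f, idx_b, fb)
            return f

        return EnergyTerm(name, tag, energy, force)

    if excluded_volume_eps > 0:
        # exclude bonded neighbours from solute-solute repulsion? keep all pairs:
        # at rest_length ~ sigma the bonded pair sits at the WCA cutoff, so the
        # bonded contribution is small and harmless; simpler and still tagged pp.
        if n_beads > 2:
            # intramolecular: direct distances, chain kept whole
            terms.append(_pair_term(bead_idx, bead_idx, "pp", "wca_pp", True, None))
        if n_solvent:
            terms.append(_pair_term(bead_idx, solv_idx, "pw", "wca_pw", False, box))
            if n_solvent > 1:
                terms.append(_pair_term(solv_idx, solv_idx, "ww", "wca_ww", True, box))

    i0, i1 = 0, n_beads - 1
    spec = CvSpec(kind="end_end_distance", endpoint_indices=(i0, i1), name="d_end")

    def cv_value(x: np.ndarray) -> float:
        d = x[i1] - x[i0]
        return float(np.sqrt(d @ d))

    def cv_gradient(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        d = x[i1] - x[i0]
        r = math.sqrt(float(d @ d))
        if r < 1e-12:
            return g
        g[i1] = d / r
        g[i0] = -d / r
        return g

    def observables(x: np.ndarray) -> dict:
        d = x[i1] - x[i0]
        return {"d_end_x": float(d[0]), "radius_of_gyration": float(
            np.sqrt(np.mean(np.sum((x[:n_beads] - x[:n_beads].mean(axis=0)) ** 2, axis=1))))}

    sys = ModelSystem(
        positions=pos,
        masses=1.0,
        group_labels=labels,
        terms=terms,
        cv_spec=spec,
        cv_value=cv_value,
        cv_gradient=cv_gradient,
        box=box,
        observables=observables,
        name="polymer",
    )
    sys.n_beads = n_beads
    sys.bond_k = bond_k
    sys.rest_length = rest_length
    return sys


# ---------------------------------------------------------------------------
# XYZ I/O for coordinates
# ---------------------------------------------------------------------------

def write_xyz(path, system: ModelSystem, positions: np.ndarray | None = None, comment: str = "") -> None:
    """Write coordinates in plain XYZ (element column = S for solute, W for solvent)."""
    x = system.positions if positions is None else np.asarray(positions)
    sym = {"solute": "S", "solvent": "W"}
    with open(path, "w") as fh:
        fh.write(f"{x.shape[0]}\n{comment}\n")
        for lab, row in zip(system.group_labels, x):
            coords = " ".join(f"{v:.10f}" for v in row)
            if x.shape[1] < 3:
                coords += " 0.0" * (3 - x.shape[1])
            fh.write(f"{sym[lab]} {coords}\n")


def read_xyz(path) -> np.ndarray:
    """Read coordinates written by :func:`write_xyz` (returns (n, 3) array)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0])
    rows = [list(map(float, ln.split()[1:4])) for ln in lines[2 : 2 + n]]
    return np.asarray(rows)
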