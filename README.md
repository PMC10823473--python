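# fisstkit

Force tempering (FISST — infinite-switch simulated tempering in force) and its
hybrid combination with replica exchange, implemented as a self-contained
sampling library with a toy Langevin dynamics engine.

## The problem

Single-molecule experiments and tension-sensor constructs probe how a
biomolecule's conformational ensemble responds to a constant pulling force *F*
applied along a collective variable *Q*(**q**) (typically an end-to-end
distance).  Simulating one trajectory per force is wasteful; worse, a pulling
bias alone cannot cross large conformational barriers.  This package is for
method developers and students of enhanced sampling who want to exercise and
validate, end to end and against exact references, the machinery that solves
both problems:

* **Force tempering.**  Instead of one force, sample the mixture ensemble

  $$p(q) \propto \int_{F_\min}^{F_\max} \mathrm{d}F\, \omega(F)\, e^{-\beta\,(U(q) - F\,Q(q))},$$

  the infinite-switch limit of simulated tempering over a ladder of forces.
  Dynamics feel the effective pulling force
  $\bar F(Q) = \int \mathrm dF\,\omega F e^{\beta F Q} / \int \mathrm dF\,\omega e^{\beta F Q}$
  along $\nabla Q$.  The weights $\omega(F)$ are learned on the fly toward
  $1/Z_q(F)$, where $Z_q(F) = \int \mathrm{d}q\, e^{-\beta U + \beta F Q}$, so
  that all forces are visited evenly.  Per-frame observable weights
  $W_F(q) = e^{\beta F Q} / \int \mathrm dF'\,\omega(F') e^{\beta F' Q}$
  then turn the single run into fixed-force averages
  $\langle O\rangle_F = \sum_t O_t W_F(q_t) / \sum_t W_F(q_t)$
  at *every* force in the range: distributions $P(Q\,|\,F)$, free-energy
  profiles $A(Q) = -k_BT \ln P(Q)$, and force–extension curves
  $\langle Q\rangle(F)$.

* **Replica exchange.**  Ladders of replicas — plain temperature ladders
  ($T_i = T_0 (T_N/T_0)^{i/(N-1)}$) or solute-tempering ladders that keep one
  thermostat temperature but scale solute–solute and solute–solvent energies by
  $\lambda^{pp}_i = T_0/T_i$, $\lambda^{pw}_i$ and $\kappa_i$ — with Metropolis
  neighbour swaps
  $\Delta = \beta_i[H_i(q_j) - H_i(q_i)] + \beta_j[H_j(q_i) - H_j(q_j)]$,
  each $H$ including that replica's own force-tempering bias.  The combination
  rescues force tempering when it is trapped behind a barrier, while exchange
  statistics stay correct because bias statistics accumulate exactly once per
  MD step, never during swap-evaluation energy calls.

Everything runs on toy model systems (a harmonic well, 1D double wells, a 3D
bead-spring polymer with repulsive solvent and a solute/solvent energy
decomposition) whose statistics are known in closed form or by 1D quadrature,
so every claim the machinery makes can be checked against an independent
oracle.

## Worked example

One force-tempered run of a harmonic spring ($U = kQ^2/2$, $k = 1$,
$\beta = 1$) predicts the tilted-ensemble mean $\langle Q\rangle_F = F/k$ at
every force in $[-2, 2]$, and the learned weights converge to the analytic
$1/Z_q(F) \propto e^{-\beta F^2/2k}$:

```python
import numpy as np
import fisstkit as fk

system = fk.make_harmonic_cv_system(stiffness=1.0, center=0.0)
state = fk.FisstState(fk.ForceGrid(-2.0, 2.0, n_points=121), beta=1.0, update_interval=500)
settings = fk.IntegratorSettings(timestep=0.2, friction=0.5, beta=1.0, seed=42, n_steps=200000)
traj = fk.simulate(system, settings, fk.FisstBias(state))

for F in (-2.0, -1.0, 0.0, 1.0, 2.0):
    print(f"F = {F:+.0f}:  <Q> = {fk.reweighted_average(traj, 'Q', F):+.3f}   (exact {F:+.3f})")

target = np.exp(-state.grid.nodes**2 / 2)
target /= state.grid.quadrature_weights @ target
err = np.max(np.abs(state.omega - target) / target)
print(f"learned omega(F) vs analytic 1/Z(F): sup relative error = {err:.1%}")
```

prints

```
F = -2:  <Q> = -1.967   (exact -2.000)
F = -1:  <Q> = -1.007   (exact -1.000)
F = +0:  <Q> = -0.014   (exact +0.000)
F = +1:  <Q> = +0.999   (exact +1.000)
F = +2:  <Q> = +2.005   (exact +2.000)
learned omega(F) vs analytic 1/Z(F): sup relative error = 1.3%
```

i.e. a single 2×10⁵-step trajectory reproduces the exact fixed-force means at
five different forces to ~1–3% of a thermal fluctuation, and the adaptive
weight estimate is within 1.3% of its analytic target everywhere on the grid.

The same workflow is available from the shell: `fisstkit run config.yaml`
executes a plain / constant-force / force-tempered / ladder run described by a
YAML config, `fisstkit analyze` produces profiles and force–extension tables
from a run directory, and `fisstkit compare` scores two runs (Jensen–Shannon
distance, Spearman rank correlation of free energies, RMSE below a free-energy
cutoff).

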