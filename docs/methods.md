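# Methods

## The sampling model

`fisstkit` samples configurations of a model system from the force-mixture
ensemble

    p(q) ∝ ∫_{F_min}^{F_max} dF ω(F) exp(-β (U(q) − F·Q(q))),

the infinite-switch limit of simulated tempering over a ladder of constant
pulling forces applied along a collective variable Q.  Three pieces make this
operational:

1. **The applied bias.**  The mixture corresponds to a bias potential
   V(Q) = −(1/β) log ∫ dF ω(F) e^{βFQ}, whose negative CV-derivative is the
   effective pulling force F̄(Q), the ω-weighted exponentially tilted mean of
   F.  F̄ is bounded by [F_min, F_max] and non-decreasing in Q (its derivative
   is β times a variance).

2. **Weight learning.**  Forces are sampled evenly when ω(F) ∝ 1/Z_q(F) with
   Z_q(F) = ∫ dq e^{−βU+βFQ}.  The estimator used is the cumulative mean over
   samples of the mixture importance ratio
   r_t(F) = e^{βFQ_t} / ∫ dF′ ω_t(F′) e^{βF′Q_t}.
   Its expectation under the instantaneous mixture is Z_q(F)/C_t for *any*
   current ω_t, with C_t independent of F; mixing adaptation phases therefore
   changes only an overall constant, never the learned shape, which is why the
   scheme is consistent even before ω converges.  ω is reset to 1/ẑ after
   every update and renormalized under the grid quadrature.  The learner is
   a strategy behind `update_weights`; alternatives can be slotted in.

3. **Reweighting.**  Each recorded frame stores Q and the log mixture
   denominator under the weights in force at sampling time, so the observable
   weight W_F(q) = e^{βFQ}/∫dF′ω e^{βF′Q} for any F on the grid can be
   recomputed after the fact; a Q-independent normalization cancels in the
   self-normalized average and is omitted.  Both conventions — per-frame stored
   denominators, or recomputation from the final (e.g. frozen) ω — are exposed
   (`weights="stored" | "final"`), because adaptive runs can legitimately be
   analyzed either way.  Reweighting refuses to extrapolate outside the grid.

**Freezing.**  `freeze` fixes ω; further update calls are no-ops (logged).
This mirrors the production protocol of learning weights during an
equilibration phase and then simulating with them fixed, which removes the
nonstationarity of an adaptive bias.

**Replica exchange.**  Replica i carries its own Hamiltonian
H_i = λ_pp U_pp + κ λ_pw U_pw + U_ww + V_i(Q) at inverse temperature β_i.
Neighbour swaps use the standard two-replica Metropolis rule
Δ = β_i[H_i(q_j) − H_i(q_i)] + β_j[H_j(q_i) − H_j(q_j)], accept with
min(1, e^−Δ); the pair schedule alternates deterministically between even and
odd passes.  On acceptance, velocities rescale by √(T_new/T_old), preserving
the Maxwell–Boltzmann marginals.  In temperature mode each replica's
force-tempering bias uses its own β_i in every tilt factor — the bias is part
of that replica's Hamiltonian, so even a pure temperature ladder is
effectively a Hamiltonian exchange.  Bias statistics accumulate in the
propagation step only: energy evaluations performed while scoring a swap
(there are several per attempt) never touch them, and the `FisstBias`
instrumentation counters let tests assert exactly that.

Per-replica weight learning is the default; `pool_statistics` switches a
ladder to one shared estimator fed by all replicas (requires a common grid
and β convention, i.e. solute-tempering ladders).

## Tunable parameters (reduced units: k_B = 1, lengths dimensionless)

| parameter | default | why |
|---|---|---|
| force grid points | 121 | fine enough that trapezoid error is far below sampling noise for the smooth integrands here |
| quadrature | trapezoid, uniform nodes | documented rule; weights sum to F_max − F_min; a single-node grid carries unit weight so the mixture degenerates to a point mass |
| `update_interval` | 500 steps | weight refresh cadence; the estimator is cumulative, so the cadence only sets bookkeeping granularity |
| timestep, friction | per fixture (below) | see the error budget |
| exchange interval | 100 steps (config default); 5 steps in the double-well study | frequent swapping approaches the rapid-switch limit, which is the efficient end for replica transport |
| ladder temperatures | geometric, T_i = T_0 (T_top/T_0)^{i/(N−1)} | near-uniform acceptance across rungs |
| histogram bins | 100 uniform over the observed range (analysis default) | profile resolution; distribution-*distance* checks instead use 6–10 coarse bins with open tails, because the χ²-noise floor of a Jensen–Shannon estimate grows as √(bins/ESS) |
| block averaging | 5 contiguous blocks | standard error of reweighted means under autocorrelation |

## Integrator error budget

The default integrator is the BAOAB splitting of underdamped Langevin
dynamics (one force evaluation and one Gaussian vector per step; velocities
initialized from Maxwell–Boltzmann at β; one explicitly seeded stream per
replica, with the exchange layer owning a separate stream).  Solving the
discrete Lyapunov equation for the one-step affine map on a harmonic well
shows that BAOAB's *configurational* marginal is exact at every stable
timestep — only velocity averages carry O(dt²) error — so on the 1D fixtures
the timestep is chosen for decorrelation speed subject to stability
(dt·ω ≤ 0.2) and to keeping the O(dt²) error of anharmonic terms small:

* harmonic fixture (ω = 1): dt = 0.2, γ = 0.5 — position integrated
  autocorrelation time γ/ω² = 0.5 time units ≈ 2.5 steps;
* plateau double well (well frequency ω = 40): dt = 0.005, γ = 20;
* polymer (WCA contact stiffness sets ω ≈ 25–40): dt = 0.005, γ = 2.

The selectable overdamped Euler–Maruyama scheme has a harmonic variance bias
of k·dt/(2γ) (about 2% at its documented default dt = 0.04, γ = 1), which the
cross-integrator agreement test takes into account by construction.

## Model systems (what the generator emulates, and what it does not)

The fixtures stand in for a solvated peptide pulled at its termini:

* **Harmonic CV system** — the Gaussian limit in which every quantity the
  sampler estimates (tilted means, Z_q(F), mixture densities) has a closed
  form; this is the main oracle-backed fixture.
* **Double well** — a two-basin conformational landscape.  The default
  `quartic` form is the textbook b((Q/a)²−1)².  The `plateau` form,
  b·tanh(((Q/a)²−1)²/c) plus an outer b·((Q/a)²−1)² confining wall, has stiff
  narrow wells separated by a broad flat barrier.  That separation matters at
  desk scale: for the quartic form the number of spontaneous barrier crossings
  per run and the number of effectively independent in-well samples both scale
  with the diffusion coefficient, so no choice of friction yields a run that
  simultaneously stays kinetically trapped *and* resolves the in-well profile.
  The plateau form decouples the attempt frequency (set by the barrier
  geometry) from the in-well relaxation (set by the well stiffness), which is
  what the hybrid-rescue study needs.  The study conditions are β·barrier = 8,
  wall sharpness c = 0.04 (well frequency 40), force range [−0.5, 0.5]
  (a ±1 k_BT tilt across the landscape), and a 4-replica ladder to T_top = 20
  exchanging every 5 steps.
* **Bead-spring polymer** — harmonic bonds plus WCA (purely repulsive
  Lennard-Jones) excluded volume, optional WCA solvent in a periodic box
  (minimum image for solvent-involving pairs; the chain itself is kept whole
  and uses direct distances).  Bonds and solute–solute repulsion are tagged
  pp, solute–solvent pw, solvent–solvent ww — the decomposition that
  solute-tempering scaling acts on.  The CV is the end-to-end distance.  With
  zero rest length and no excluded volume it reduces to the ideal Gaussian
  chain, ⟨d²⟩ = 3(n−1)/(βk).

None of these fixtures have the ruggedness, dimensionality, hydrodynamics, or
force-field realism of solvated peptides.  Passing tests therefore validate
the *algorithmic machinery* — reweighting identities, weight-learning
convergence, exchange detailed balance, bookkeeping — not the physical
accuracy of any molecular prediction; microsecond all-atom behaviour is out
of scope by construction.

## Numerical choices

* All integrals over F are evaluated in log space with a max-shift
  (log-sum-exp over quadrature nodes); β·F·Q beyond float range is safe, and
  F̄ is a convex combination of nodes by construction.
* A normalized single-node (degenerate) grid is pinned to ω ≡ 1 exactly, so a
  degenerate force-tempered run is bitwise identical to the constant-force
  protocol with the same seed — the single-force reduction used as an exact
  regression anchor.
* Normalization skips sub-roundoff shifts (|log norm| ≤ 1e-14) so that it is
  exactly idempotent and restart round-trips reproduce ω bit for bit.
  Restart files are self-describing JSON (format version, grid, per-node ω
  and ẑ at full precision, sample count, frozen flag, pending buffer);
  corrupted or version-mismatched files raise a parse error rather than
  silently resetting.
* Empty histogram bins carry NaN free energies, never infinities; comparison
  statistics drop missing bins pairwise and report the count, and the
  RMSE-below-cutoff comparison defines its region on the *reference* profile's
  bins.
* Jensen–Shannon distance is fixed to base-2 logarithms and the square root of
  the divergence (bounded by 1).
* Trajectories are columnar TSV with a JSON metadata header; floats are
  written with 17 significant digits and parsed in round-trip mode, so TSV
  round-trips are bit-exact.

## Design choices where the design was open

* The exact weight-learning estimator is not uniquely determined by the
  target ω ∝ 1/Z_q; the cumulative-mean mixture-importance estimator above was
  adopted for its phase-mixing consistency (documented under "Weight
  learning") and implemented behind a single function so alternatives can be
  compared.
* The solute–solvent scaling λ_pw defaults to √(T_0/T_i); κ is user-supplied
  per replica, with `rest3_kappa(m) = 1 + 0.005(m − 3)` for m > 3 available
  as a helper.  The toy systems have one non-bonded interaction class, so κ
  multiplies the whole pw term rather than only a non-electrostatic part — a
  stated limitation of the fixtures, not of the exchange machinery.
* Exchange Δ uses the standard two-replica Metropolis form stated above.
* Convergence-curve monotonicity is asserted on a window-5 moving average
  with a 0.05 k_BT per-step allowance: the prefix RMSE carries residual
  basin-population noise that smoothing cannot fully remove.
* Burn-in: profile analyses of ladder runs discard the first 10% of frames;
  replicas all start in one basin and the discard removes that transient.

## Known limitations

* Quadrature oracles are 1D (CV-space) only; the polymer is validated by
  direct sampling statistics instead.
* No two-dimensional infinite-switch tempering over force × temperature; the
  hybrid here is force tempering composed with discrete replica exchange.
* Serial execution defines correctness; there is no MPI contract.
* No constraints, no pressure coupling, no multiple-time-stepping; the toy
  engine is not a general-purpose MD code.
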