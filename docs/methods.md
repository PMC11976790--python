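# Methods

## Dynamics

The engine integrates overdamped Langevin dynamics for N particles in 2D or
3D with the Euler–Maruyama scheme. Per step Δt:

* translation: Δr = γ_t⁻¹ (F_act ê + F_WCA + F_ext) Δt + √(2 k_B T γ_t⁻¹ Δt) ξ,
  ξ ~ N(0, 1) per component;
* rotation (2D): the director angle θ gains γ_r⁻¹ M_z Δt plus Gaussian noise
  of variance 2 k_B T γ_r⁻¹ Δt. In 3D the director is rotated by the
  increment vector ω Δt + noise, ω = γ_r⁻¹ **M**, and renormalized.

Assumptions: no inertia (Stokes regime), no hydrodynamic interactions, noise
white and isotropic, frictions constant per particle type. Reduced units
with k_B = 1 throughout; a natural reading is lengths in particle radii,
energies in k_B T at room temperature, times in units set by γ_t.

Key consequences used for validation (2D): D_t = k_B T/γ_t,
D_r = k_B T/γ_r, persistence time τ_r = 1/D_r, swim speed v = F_act/γ_t,
and the active MSD
4 D_t t + 2 v² τ_r² [t/τ_r + e^(−t/τ_r) − 1]. Because the 2D angle performs
an exact Gaussian random walk, the orientation autocorrelation
⟨ê(t)·ê(0)⟩ = e^(−D_r t) holds without time-discretization bias; the
translational discretization error is O(D_r Δt) relative and is kept ≪ 1 by
the default step sizes.

Numerical choices:

* **Interactions.** WCA only (purely repulsive Lennard-Jones, cutoff
  2^(1/6) σ), all-pairs O(N²) with minimum-image convention under periodic
  boundaries. Forces are capped below 0.5 σ separation (with a warning) so
  pathological initial overlap cannot produce infinities; a per-step WCA
  displacement > 0.1 σ triggers a one-time "reduce Δt" warning.
* **Boundaries.** `periodic` (positions wrapped, image counts tracked so
  displacement statistics use unwrapped coordinates), `reflective` (mirror
  reflection — chosen over a soft wall force so that positions are strictly
  inside the box at all times), and `open` for free-space validation runs.
* **Rigid rod.** A chain of beads moved as one overdamped rigid body: the
  net bead force translates the center with friction γ_t^rod, the net
  z-torque rotates it with γ_r^rod, bead positions are reconstructed from
  (center, angle) each step, so the rod is rigid to machine precision.
* **Direction override.** An action carrying `new_direction` replaces the
  torque update for that step (applied at every inner step of the slice).
* **RNG.** One counter-based PCG64 generator owned by the engine, seeded
  from the run configuration and recorded in trajectory metadata.

## Control layer

A *slice* is the interval between control queries: the force function is
asked once per slice for fresh actions, which are held constant over
`steps_per_slice` inner integration steps. The force function is the single
narrow interface between environment and control: it receives colloid
snapshots (mutating them cannot affect the engine) and returns one action
per colloid; unregistered particle types are passive.

Reward timing follows the s_t, a_t → s_{t+1}, r_{t+1} convention: the task
reward computed when slice t+1's state is observed closes step t. The final
action of an episode is closed by an explicit `finalize` call on the last
state. Change-type observables and gain-type tasks initialize their history
to the current value, so first-slice signals are exactly zero rather than
spurious.

## Training

Networks are multilayer perceptrons (default 2 × 128 tanh units; a
shared-trunk and a disjoint actor/critic variant) with hand-written
backpropagation, optimized by Adam (default η = 10⁻³). No autodiff
framework is used; the analytic gradients are tested against central
finite differences.

Per update (one per episode, or per `update_every` slices in continuous
mode), all particles of a shared-policy group are pooled into one batch:

1. returns G_t by the exact backward recursion; advantages by GAE(λ)
   (default γ = 0.99, λ = 0.95, terminal bootstrap 0) or plain G − V;
2. optional per-batch advantage standardization (default on; a constant
   batch maps to zero advantages rather than dividing by ~0);
3. actor loss: vanilla policy-gradient surrogate −Σ log π(a_t|s_t) A_t, or
   the PPO clipped surrogate with ε_clip = 0.2 and 4 epochs per batch;
   probabilities are clamped at 10⁻⁸ before logs;
4. an optional entropy bonus (default coefficient 0.01) enters the gradient
   only — the logged actor loss is the bare surrogate, so a fully
   uninformative batch logs exactly zero;
5. critic regression: mean squared error against G_t.

A team-average reward mode replaces each particle's reward with the group
mean (cooperative setting). Exploration (probability ζ decaying as
ζ' = e^(−εt/T) ζ) substitutes uniform random actions; such steps stay in
the training batch with the policy's log-probability of the executed action
(configurable, a deliberate off-policy simplification). RND intrinsic
rewards (frozen random target vs trained predictor, 1 × 64 hidden units,
16-dim embedding, MSE, Adam 10⁻³) are added to the task reward with weight
0.1 by default; a memory variant trains on minibatches (128) from a
4096-state FIFO so previously visited states stay familiar.

Reproducibility: every randomness stream of episode k (engine noise, action
sampling, exploration, RND) is seeded from `SeedSequence([master, k,
stream])`. A (configuration, seed) pair therefore fixes the entire run
bit-for-bit, and a checkpoint needs only network parameters, Adam state and
the episode index to resume exactly — verified by an exactness test.

## Synthetic scenarios

The generator emulates idealized laboratory situations, not any particular
experiment:

* `free-diffusion` / `abp-gas` — non-interacting passive/active gases whose
  statistics have closed forms; these anchor the engine tests.
* `chemotaxis-arena` — a static Gaussian concentration field
  c(x) = c₀ e^(−|x−x₀|²/2σ_c²) (σ_c = 8, c₀ = 1), ten swimmers starting at
  distance ≈ 10 from the source with random orientations; swim speed 10,
  D_r = 0.1, slice time 0.1, so one deterministic body move per slice and a
  concentration gain of order 0.1 per slice up-gradient. Agents sense only
  the scaled concentration change (one number); the reward is the
  positively clipped gain (run-and-tumble-style reinforcement; a signed
  variant is switchable).
* `rod-arena` — a 7-bead rigid rod with WCA pushers rewarded by the rod's
  signed angular velocity.
* `bandit` — a two-armed bandit wrapped in the engine interface (the
  particle's x coordinate encodes the pulled arm); the independent oracle
  for the policy-gradient mathematics. The bandit declares
  standardization off and entropy 0 (with single-sample batches, a
  deterministic policy is a fixed point of the standardized update, which
  would mask convergence); VPG uses η = 0.05, PPO η = 0.01 since four
  epochs per single-sample batch at 0.05 can lock in the wrong arm before
  the critic calibrates.

What a green test does establish: the integrator reproduces exact
active-matter statistics; the RL mathematics matches brute-force sums; the
full stack turns a diffusive swarm into a chemotactic one. What it does not:
hydrodynamic realism, robustness to sensor noise models beyond thermal
motion, or transfer to any specific experimental device.

## Limitations

* Overdamped dynamics only; no hydrodynamic (lattice-Boltzmann or Oseen)
  coupling; no hardware/experiment connections.
* Discrete action sets only; MLP policies only (no graph/transformer
  architectures).
* All-pairs interactions are O(N²) — fine at the intended desk scale
  (N ≲ a few thousand interacting particles).
* Continuous-mode updates bootstrap chunk ends with value 0 rather than the
  critic's estimate; trailing partial chunks before a kill switch are
  discarded without an update.
* The rigid rod is 2D only.
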