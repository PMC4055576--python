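# Methods

## Model

A population of N individuals is a simple undirected graph (optionally a
multiplex: L layers over one node set). Each node holds exactly one of m
states (1-of-m coding). Parameters are node-independent:

* **Γ** (m×m, probabilities or rates): γ_kl is the chance that a contact of
  a receiver in state k with a sender in state l transmits. Diagonal
  entries are allowed — a transmitted copy of the receiver's own state
  still occupies the uniform choice and thereby dilutes competitors.
* **Δ** (m×m): spontaneous ("loaded dice") transition probabilities; in
  probability form the diagonal absorbs the remainder so every row sums
  to 1; in rate form the diagonal is zero.
* **Θ** (m×m×m, 0/1): θ^k_rl = 1 iff exposure of a node in state k to a
  transmitted state r makes it adopt state l; exactly one l per (k, r);
  identity (l = r) by default. Fractional Θ weights are out of scope.

One synchronous step, per node, reading only the step-start configuration:
roll the dice (row k of Δ); if it moves the node, done. Otherwise every
neighbor attempts one directed transmission; among the successful
("infectious") links one is chosen uniformly; Θ maps its transmitted state
to the adopted state; with no infectious link the node keeps its state. A
spontaneously moved node still transmits its step-start state to others
within the step — the synchronous semantics the reactive process implies.

## Adoption probabilities

For a receiver in state k with n_l neighbors in state l, write
s_l ~ Binomial(n_l, γ_kl) for the independent per-state success counts and
S = Σ s_l. Then

* h = P(S = 0) = Π_l (1 − γ_kl)^{n_l} (no-adoption probability),
* q_l = E[s_l/S ; S > 0] (state l wins the uniform choice),
* q̂_l = Σ_r θ^k_rl q_r (stimulated adoption; mass-preserving).

Exact backends:

1. **Event enumeration** — the literal sum over the 2^n binary
   infectious-link vectors (n ≤ 20, chunked to bound memory).
2. **Polynomial integral** — from s_l/S = ∫₀¹ s_l x^{S−1} dx and the
   binomial generating function,

       q_l = ∫₀¹ n_l γ_l (1−γ_l+γ_l x)^{n_l−1} Π_{j≠l} (1−γ_j+γ_j x)^{n_j} dx,

   a degree-(n−1) polynomial integrated exactly by Gauss–Legendre with
   ⌈n/2⌉+1 nodes; valid to degrees in the thousands. The two backends are
   algorithmically independent and cross-checked to 1e-12.

For probability-vector (deterministic) inputs the exact value is the
configuration sum over all m^k neighbor-state assignments weighted by the
product of marginals (the independence assumption). Two routes:

* the literal configuration × event double sum, O(m^k 2^k), guarded by a
  10^7-term budget and kept mainly as the reference;
* an identical-by-mathematics fast route: the configuration sum enters
  only through the joint distribution of the neighbor-state count vector,
  built by a dense shift-add convolution over neighbors, then contracted
  against a cached per-(Γ-row, degree) table of exact count-vector
  results. Cost O(k·(k+1)^m) per node. Equality with the literal double
  sum is asserted in the tests. Neighbor vectors are renormalized inside
  the convolution: without this, a row-sum rounding error of ε is
  amplified by a factor ≈ degree per solver step and the fixed-point
  iteration blows up after ~20 steps.

**Approximation.** The random share s_l/S is replaced by the ratio of
expectations:

    q*_l = (n_l γ_kl / Σ_r n_r γ_kr) · (1 − h)

and, for probability-vector inputs, n_l → Σ_j p_j^l with
h = Π_j (1 − Σ_r γ_kr p_j^r). h is always computed by its exact product
form; only the share is approximated. The form is exact in three limits —
a single transmissible state (product form), all γ equal (the share is
n_l/n regardless of S), and at most one neighbor — and O(m·k) at any
degree.

Measured accuracy (exhaustive over count vectors, m = 3, n ≤ 10, random
rows): worst absolute error 0.017 for γ ≤ 0.3; for unrestricted γ ≤ 1 the
worst error is ≈ 0.108, at strongly heterogeneous near-1 rows such as
counts (1,0,7) with γ ≈ (0.97, 0.88, 0.17) — slightly above the 0.1 one
might hope for, which is why the tests pin the 0.02/γ≤0.3 envelope and the
exactness limits rather than a full-range bound. The error at fixed points
of the competition models is far smaller off the symmetric diagonal
(< 1e-3) because a clear winner removes the competition that the share
approximation distorts.

## Deterministic solver (NLDS)

Taking expectations under node-independence gives the per-node update of
the N×m probability field P:

    p'_i[k] = Σ_{l≠k} δ_lk p_i[l]
            + Σ_l p_i[l] δ_ll q̂_i^{l→k}
            + p_i[k] δ_kk h_i^k,

with q̂, h computed from the neighbors' current vectors by either backend.
Rows remain stochastic to 1e-9 (asserted after every step; conservation is
exact up to rounding because Σ_l q_l + h = 1). Fixed points are found by
plain iteration (default tol 1e-10 on the L∞ step change, max 1e5 steps);
non-convergence (e.g. while cyclic dynamics are still swinging, or on the
very slow near-diagonal manifold of the contact-only competition model,
where the per-step contraction factor can be ≈ 0.99997) is reported via
`converged=False` with the residual history, never raised.

Multiplex: links from all layers compete in one pooled uniform choice,
each with its own layer's Γ^(α); h factorizes over layers. When each
contagion lives on exactly one layer this reduces to the per-layer product
forms (asserted against a hand-coded implementation); with one layer it is
exactly the single-layer step.

## Continuous time

With probabilities replaced by rate·dt and dt → 0, simultaneous
transmissions vanish and the uniform choice disappears; for identity Θ the
contact term of dp_i[k]/dt depends only on neighbors' state-k mass. The
general-Θ right-hand side used here is the unique bilinear form whose
identity-Θ specialization has that property and whose rows sum to zero;
first-order consistency of the discrete solver with the RK4 reference
(empirical log-log slope ≈ 1.01 on the 6-node star) confirms the
reconstruction. Integration is fixed-step RK4, default dt = 0.01, chosen
over adaptive stepping so order-of-consistency measurements are clean.
The homogeneous mean-field Maki–Thompson reduction (k-regular graph,
uniform initial conditions) collapses the full system node-for-node:

    di/dt = −λk·i·s,  ds/dt = λk·i·s − αk·s(s+r) − σs,
    dr/dt = αk·s(s+r) + σs.

## Stochastic simulator and RNG discipline

All randomness of a step is drawn as arrays indexed by node or directed
edge, so the update cannot depend on a node iteration order. The uniform
choice among a receiver's infectious links is implemented as "smallest
i.i.d. key on a successful link", which is exactly uniform and
vectorizes. Ensembles spawn one child seed sequence per run from the base
seed; identical seeds give identical runs.

## Preset zoo

SIS, SIR, SIRS, Maki–Thompson with forgetting (σ = 0 recovers the original
model; Θ deviates from identity only in the spreader-meets-spreader slice),
the two-contagion competition model with spontaneous recovery, its
contact-only variant (recovery by contacting susceptible nodes, Δ = I), a
three-innovation cycle model (no susceptible state, full Γ incl. diagonal),
and the two-layer multiplex competition. All presets validate and, having
no real multi-state competition after Θ composition (or none at all), run
through the generic engine identically (1e-12) to their hand-coded
closed-form updates — only the two-contagion competition models actually
exercise the approximation.

The bundled three-innovation transmission matrix

    [[0.1, 0.7, 0.2],
     [0.2, 0.1, 0.7],
     [0.7, 0.2, 0.1]]

is a **synthetic** default: large entries, full matrix, the row maxima
tracing the 3-cycle A→B→C→A, producing pronounced damped oscillations of
the deterministic field and sustained cyclic patterns in lattice
simulations. Callers studying a specific system should pass their own
matrix to `preset_three_innovations`.

## Synthetic experiments: what a green test does and does not establish

The scan experiments iterate both deterministic backends to their
macroscopic fixed points from three seeded random initial assignments on
the 6-node complete and star graphs and the 3×3 periodic lattice
(δ₁ = δ₂ = 0.2, defaults chosen once), and record the Euclidean norm of
the difference of the macroscopic fraction vectors. Green means: the share
approximation does not move macroscopic fixed points off the symmetric
diagonal (error < 1e-3, winner-takes-all), and stays below 0.05 in the
low-τ and near-diagonal regions of the contact-only variant. It does not
establish anything about graphs with hubs of very high degree beyond the
polynomial backend's reach of the *stochastic* exact computation, nor
about node-dependent parameters (out of scope).

The lattice comparison runs 200 seeded stochastic realizations of the
three-innovation model on a 32×32 periodic lattice for 30 steps against
the approximated deterministic trajectory from the same initial
assignment. Measured outcome: the ensemble mean deviates from the solver
by up to ≈ 0.011 — about 1.7× the 3-stderr Monte-Carlo band — from step
~7 on. The gap is unchanged when the solver uses the exact adoption
backend (approx-vs-exact differ by only ≈ 0.0025), so it is the
node-independence assumption breaking on a locally correlated lattice,
not the share approximation and not a simulator defect (the simulator's
one-step distributions pass chi-square tests against the exact
computation at α = 0.001). The same family of effects appears on tiny
graphs over long horizons: small-graph SIS ensembles drift below the
deterministic curve because runs absorb at the all-susceptible state
while the solver never does. Figure-resolution agreement (~1 %) between
solver and ensemble is real; statistical indistinguishability at the
3-stderr level is not a property of this class of models on clustered or
tiny graphs, and the corresponding acceptance test records that honestly.

## Numerical choices

* Conservation asserted at 1e-12 in unit computations, 1e-9 along
  pipelines.
* Enumeration guard n ≤ 20; literal double-sum budget 10^7 elementary
  terms; both overridable.
* Counts/q tables cached per (Γ-row, degree); cache cleared beyond 512
  entries.
* Degenerate inputs: zero-degree nodes have h = 1 and never adopt;
  all-zero Γ rows give q = 0 without division by zero; probability-form
  and rate-form specs are distinct modes and mixing them raises.
* Edge-list I/O: arbitrary integer labels compacted to 0..N−1 with the
  original ids retained; duplicate/reversed edges deduplicated;
  self-loops rejected; disconnected inputs accepted with a warning (the
  dynamics are well defined per component).

## Known limitations

* Deterministic solver ≠ ensemble mean on small or strongly clustered
  graphs (see above); no pair approximation is provided.
* No Gillespie/asynchronous dynamics — the finite synchronous step *is*
  the object of study.
* No heterogeneous (degree-class) mean field; only the full per-node
  system and the homogeneous reduction.
* Weighted or directed graphs and node-dependent parameters are not
  supported.
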