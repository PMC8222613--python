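# Methods

This note records the models implemented in `dcmsearch`, the conventions
and defaults it freezes, and the choices made where the underlying methods
literature leaves the design open.

## Bilinear DCM forward model

Neural dynamics follow the bilinear approximation
`dx/dt = (A + Σ_k u_k B_k) x + C u` around the resting expansion point
`f(0,0) = 0`. Conventions:

* **Direction.** `A[i, j]` is the influence of region *j* on region *i*
  (columns are sources). The literature is not consistent here; this
  package states and tests one convention.
* **Self-connections.** Diagonal entries of `A` (and of each `B_k`) are
  unitless log-scaling factors of a fixed −0.5 Hz decay: the effective
  self-connection is `−0.5·exp(a_ii + Σ_k u_k b_ii,k)`, negative for any
  real parameter value, so self-inhibition is structural. Off-diagonal
  entries are rate constants in Hz.

Each region's hemodynamics follow the Balloon–Windkessel model (signal
decay κ = 0.64 s⁻¹, feedback γ = 0.32 s⁻¹, transit time τ = 2 s, stiffness
α = 0.32, resting oxygen extraction E₀ = 0.4, neurovascular efficacy 1,
venous volume fraction V₀ = 0.04; all per-region overridable). The BOLD
observation uses the classic coefficients k₁ = 7E₀, k₂ = 2,
k₃ = 2E₀ − 0.2, scaled to percent signal change. All constants live in
`HemodynamicParams` so they are auditable in one place.

**Integration.** The joint neural + hemodynamic system is integrated with
a fixed-step classical Runge–Kutta (RK4) scheme at microtime resolution
TR/16, holding stimuli constant within a microtime bin; flow, volume and
deoxyhemoglobin are integrated in log space so positivity is structural.
RK4 was chosen over a local-linearization update because at the same step
size it is strictly more accurate and simpler to verify; halving the step
changes predicted BOLD by < 10⁻⁷ (relative L2) on the 4-region test model,
comfortably inside the 10⁻³ acceptance band. A diverging trajectory (e.g.
inflow driven to zero, which log-states cannot represent) is detected by a
state-magnitude guard and reported as an `IntegrationError` naming region
and scan. The integrator core is JIT-compiled (numba) and evaluates
batches of parameter sets in one call, which is what makes
finite-difference Jacobians affordable.

## Variational Laplace

The free parameter set of a structure comprises every present `A` entry
(the diagonal always), present `B`/`C` entries, and per-region log-scaling
parameters for κ and τ. Default priors (zero-mean, diagonal):

| block | variance | rationale |
|---|---|---|
| A off-diagonal | 0.5 | the 8/n² convention at n = 4 |
| A self-scaling | 1/64 | self-decay stays near −0.5 Hz |
| B, C | 0.25 | modulatory/driving effects beyond ~1 Hz are implausible |
| hemodynamic scalings | 1/256 | tight around the published defaults |

Observation noise is i.i.d. Gaussian with a single log-precision λ
(hyperprior N(0, 16), capped at ±16 so noiseless data cannot overflow the
precision). The loop is Gauss–Newton ascent on Fe with Levenberg-style
damping (step accepted only if Fe increases; damping ×4 on rejection, ÷2
on acceptance), interleaved Newton updates of λ, and finite-difference
Jacobians (forward differences, step 10⁻⁴, one batched integrator call per
iteration). Convergence: |ΔFe| < 10⁻² for three consecutive iterations, or
a local optimum (no uphill step exists), or 128 iterations (then the
best-so-far estimate is returned flagged unconverged). The Fe trace is
non-decreasing over accepted steps by construction.

`Fe = accuracy − KL(q ∥ prior)` with the accuracy term
`−½[N log 2π − N λ + e^λ (e'e + tr(Σ_q J'J))]` plus the λ hyperprior
penalty; λ is point-estimated (no Laplace correction over λ), which is
documented as a simplification.

**Per-parameter probability.** `p = Φ(|mean|/sd)` — the posterior
probability that a parameter shares the sign of its posterior mean
(`p = 1` when sd = 0 and mean ≠ 0). Note this functional is ≥ 0.5 by
construction; with real posteriors the GA′ drop threshold of 0.3 can only
fire on probabilities produced by other means (e.g. the synthetic
landscapes below). This tension is inherited from the thresholds
themselves and is recorded rather than resolved.

## Bayesian model reduction

For a reduced prior that only shrinks prior variances, the reduced
posterior and the log-evidence difference are closed-form functions of the
full prior, full posterior and reduced prior precisions
(`P_qr = P_q + P_r − P_0`, etc.). Exactly zero reduced variances are
handled as capped precisions (1/10⁻¹⁰) in the diagonal case; singular
precisions fall back to pseudo-inverses with a warning. The implementation
is exact for linear-Gaussian models — verified against directly computed
analytic marginal likelihoods to < 10⁻⁶ — and is the standard fast
approximation for DCM, where the same caveat applies as everywhere: the
reduced posterior is assumed Gaussian around the full model's optimum.

## Search algorithms

All searches act on bitvector codes over the free bits of a constraint
space and consult an `EvidenceOracle` (table lookup, live VL, or BMR from
an estimated full model). Caches guarantee a model is never scored twice;
N counts unique evaluations.

* **GES** alternates a removal phase and an addition phase (all valid
  one-connection-changed structures, move while the best neighbor
  improves) until a full cycle yields no improvement. The first phase is
  removal; ties break to the lowest bitvector.
* **GHD** evaluates the whole Hamming-distance-1 neighborhood (removals
  and additions together) each iteration and moves to the best improving
  neighbor.
* **GA** starts from one random model plus three mutated variants; each
  generation produces 16 offspring by two-point crossover between two
  random survivors (crossover points uniform without replacement) and
  mutation with probability 0.5 flipping 2–8 uniformly chosen bits.
  Offspring violating structural constraints or duplicating any code ever
  considered are regenerated ("a new model is generated"), with a bounded
  number of attempts before the generation terminates early with a
  warning. The best 4 of the 20 survive; ties keep incumbent survivors
  (elitist and deterministic — without this, equal-evidence models in the
  same Hamming shell churn the survivor set and the stop rule never
  fires). The run stops when the survivor set is unchanged for three
  consecutive generations (the stop rule is ambiguous between
  survivor-set stability and no-new-best; survivor-set stability is
  implemented).
* **Optimized variants.** The running mean of each connection's posterior
  probability is maintained over all evaluated models *containing* that
  connection. GES′/GHD′ exclude from removal any connection with running
  mean ≥ 0.9 (additions are never blocked; whether they should be is
  unstated and left alone). GA′ replaces a candidate when the running-mean
  probabilities of its contained connections *average* below 0.3, with a
  fresh mutant of the population. The per-connection reading (replace if
  any single contained connection is below 0.3) was rejected: under
  saturated probabilities it replaces essentially every candidate,
  disabling crossover and making GA′ strictly worse than GA — the
  opposite of the behavior the optimization is meant to produce.
* **Post-hoc pruning** greedily removes, via BMR, the free parameter whose
  removal most increases the reduced evidence, until no removal improves
  it. It costs no model estimations (N is reported as BMR evaluations
  separately) and, because it operates purely on shrinkage priors, its
  result may violate structural constraints such as
  modulation-requires-connection; this matches how post-hoc selection
  behaves in practice and is documented rather than patched.

The characterization harness runs each algorithm repeatedly (default 20
runs) with randomized initialization and reports mean and SD of dFe
(free-energy deficit to the space's best model), Hd (Hamming distance to
it) and N.

## Model families and group inference

Fixed-effects BMS is the softmax of summed log evidences
(overflow-guarded). Random-effects BMS Gibbs-samples subject-level model
assignments and population frequencies under a Dirichlet(α₀ = 1) prior
(default 10,000 sweeps, 1,000 burn-in); exceedance probability is the
posterior frequency with which a model/family has the largest population
frequency. Family comparison first aggregates model evidence into family
evidence by log-sum-exp minus log family size (a uniform within-family
prior, correcting for unequal family sizes).

The semantic-decision scheme builds 27 base modulation patterns as the
cross of three 3-level questions — which task modulates (Pictures / Words
/ both), which side (left / right / both) and which level (ventral /
dorsal / both) — with the chosen conditions modulating the
self-connections of the intersection of the side and level region sets.
Each pattern carries 2⁸ = 256 endogenous variants; each partition splits
the 27 patterns into three families of nine. A found model's family credit
is the fraction of agreeing modulation bits against each base pattern,
computed over *all* free modulation bits (the alternative — only bits
present in either model — is noted as an open choice); maximal-agreement
patterns split credit equally across their families.

## Parametric empirical Bayes

The second level treats each subject's posterior mean as a Gaussian
observation of `X·β` with covariance `Σ_i + exp(−γ)·I`: subject posterior
uncertainty plus one isotropic between-subject variance component. `X`'s
first column is the constant (commonalities); covariates (e.g. a
laterality index) are mean-centered so the constant carries the group
mean. Given γ everything is conjugate, so the β posterior and second-level
free energy are closed-form; γ is point-estimated by bounded scalar
maximization of that free energy (γ ∈ [−8, 8], hyperprior N(0, 16)). This
is deliberately the simplest standard hierarchical form; richer precision
parameterizations (per-block components, full covariance) are out of
scope. First-level posteriors are never modified. β priors default to
variance 1 per effect.

Nested group models are scored by BMR on the β posterior. Automatic search
greedily prunes the group-mean effect whose removal most increases the
second-level Fe. Topological search (GES/GHD initialized at the full
model, GA randomized) runs over presence bits of group-mean effects only —
by default the modulatory ones, matching how group-level structure
comparisons are usually reported — and never mutates covariate effects.

## Synthetic landscapes

`generate_landscape` scores every valid model of a constraint space as
`Fe = fe_base − gain·Hd(model, optimum) + noise`, with gain = 3 nats per
differing bit and a planted optimum (random valid bitvector unless given).
Noiseless (the default), the landscape is exactly unimodal and
corr(dFe, Hd) = 1. A target correlation ρ < 1 derives the noise SD from
`ρ = gain·sd(Hd) / sqrt(gain²·sd(Hd)² + σ²)` over the exhaustively
enumerated space; per-model noise is clipped below that model's distance
penalty so the planted optimum always keeps strictly maximal Fe. The
achieved correlation is validated and an infeasible request (explicit
noise too large for the requested ρ) raises with the achieved value. The
rugged variant adds rewards of 1.4·gain for jointly flipping planted bit
pairs — large enough that the double flip is a local optimum, small enough
never to beat the planted one.

Synthetic per-parameter probabilities are an invention of this package
(real probabilities come from DCM posteriors): a logistic of ±sharpness,
high for bits present in the optimum and low for absent ones, saturating
to {1, 0} as sharpness grows. They exist to make the probability-guided
search variants testable; nothing about their calibration mimics real
posteriors, and in particular they can fall below 0.5, which real
sign-probabilities cannot.

## The synthetic benchmark and what passing tests show

`semantic_benchmark` emulates the shape of the semantic-decision
experiment: 4 frontal regions (lvF, ldF, rvF, rdF), "Task" driving all
regions (C = 0.3 Hz), "Pictures"/"Words" modulating self-connections,
10-s task blocks in 20-s cycles with the two modulatory conditions
alternating, TR 3.6 s (the emulated experiment's repetition time), 200
scans, and additive white Gaussian noise calibrated to SNR 1 (pooled
signal SD over noise SD). Ground-truth couplings are drawn per seed from
±0.2–0.5 Hz (A), ±0.3–0.6 Hz (B diagonal) and screened for dynamical
stability (effective Jacobian eigenvalues < −0.15 under every on/off
combination of the modulatory inputs) and hemodynamic integrability;
implausible draws are rejected and redrawn.

The semantic constraint space fixes the four "crossed" endogenous
connections (lvF↔rdF, ldF↔rvF) off — an assumption, since only the *count*
of eight free endogenous connections is established, not their identity —
leaving the dorsoventral and homotopic connections free, and places the
eight free modulation bits on the self-connections for the two modulatory
conditions. Both choices are configurable through `ConstraintSpec`.

What the benchmark does *not* emulate: physiological (non-white,
non-isotropic) noise, scanner drift and confounds, regional variation in
hemodynamics beyond the estimated κ/τ scalings, event-related designs, and
between-subject structural variability. Parameter-recovery results on it
(pooled Pearson r ≈ 0.85 between generative and posterior-mean A/B/C
parameters across a fixed 5-seed suite at SNR 1; individual seeds range
roughly 0.62–0.97, limited by genuine posterior non-identifiability at
this noise level rather than by the optimizer — truth-initialized runs
reach the same or lower free energy) therefore bound what can be expected
of well-behaved data, not of arbitrary real acquisitions.

## Numerical notes and limitations

* Bitvector order is frozen: free off-diagonal `A` entries row-major, then
  `B` per modulatory condition row-major, then `C` per driving condition.
  Database round-trips preserve structures bit-exactly.
* Fe ties for "best model" break to the lowest bitvector, with a warning.
* `count_models` returns exact counts also under
  modulation-requires-connection (product over gating groups), so it
  always agrees with enumeration.
* The RFX Gibbs sampler is O(subjects × models) per sweep; family-level
  comparisons aggregate first, so the sampler runs over 3 columns.
* VL assumes i.i.d. noise with one shared precision across regions;
  per-region precisions are a straightforward extension not implemented.
* BMR (and therefore post-hoc pruning, the BMR oracle, and PEB search)
  inherits the Gaussian-reduction approximation; for strongly nonlinear
  effects the reduced evidence can deviate from a direct VL fit of the
  reduced model. The rank-order agreement of the two routes is exercised
  in the test suite on small spaces, not assumed.
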