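# Methods

## Model

All built-in systems are elementary mass-action networks in µM and seconds:
a reaction of molecularity m carries a rate constant in µM^(1−m) s⁻¹, the
flux of reaction j is v_j = k_f,j ∏ x_r^a_rj − k_r,j ∏ x_p^b_pj, and the
dynamics are dx/dt = N v(x) with N the integer net-stoichiometry matrix.
No saturable (Michaelis–Menten) term appears anywhere: every step in the
fusion chemistry is written as an elementary binding or unbinding event.
Conserved moieties are the left null space of N, computed exactly over the
rationals (sympy) and canonicalized by row reduction to primitive-integer
form; with the species ordered as built this reproduces the protein
moieties one expects (e.g. SNAP25 + tSNARE + FHC, and MUNC18 + Smc + FHC\*\*
for the MUNC18 moiety).  Clamped species (buffered Ca²⁺) and species with a
zeroth-order source are excluded from the moiety computation, since holding
a concentration fixed or injecting it breaks the corresponding balances.

The regulated system composes optional blocks on the fundamental two-step
core:

* **Complexin** — FHC + complexin ⇌ FC, with FC terminal (the clamp role
  only; nothing unclamps FC in this model).
* **Ca²⁺/synaptotagmin** — four sequential single-ion binding steps
  Ca + Syt ⇌ CaS ⇌ … ⇌ Ca₄S with shared rates (a configurable
  cooperativity factor can grade them), then Ca₄S + tSNARE ⇌ Tsc,
  Ca₄S + FHC ⇌ FHC\*, and Tsc + VAMP2 ⇌ FHC\*.  Sequential single-ion
  binding is the minimal scheme consistent with a synaptotagmin that
  carries four calcium ions; the intermediate stoichiometry is not
  otherwise constrained.  Ca²⁺ is either clamped at a constant
  concentration (the in-vivo balance assumption) or driven by a
  rectangular recruitment pulse s(t) (amplitude 10 µM/s, onset 0, duration
  1 s by default).
* **MUNC18** — MUNC18 + FHC ⇌ FHC\*\* and the irreversible
  MUNC18 + syntaxin → Smc (dissociation of the closed-conformation complex
  is negligible against binding).
* **Syntaxin self-association** — stepwise oligomers syntaxinₙ + syntaxin ⇌
  syntaxinₙ₊₁ up to n_max (default 5, i.e. four oligomer species).

The fusion readout is always [FHC] + [FHC\*] + [FHC\*\*].

Default initial concentrations sit inside the physiological brackets used
throughout (VAMP2 0.2–30 µM from vesicle-pool counts, SNAP25/syntaxin
0.1–100 µM, MUNC18 1–30 µM).

## Integration and steady states

Integration uses scipy's LSODA with the analytic Jacobian of the network
(rel_tol 1e-8, abs_tol 1e-10 by default).  Every accepted trajectory passes
a conservation audit (< 1e-6 relative drift per moiety); negative
excursions below 100× the absolute solver tolerance (scaled by the state
magnitude) abort the run, smaller ones are clipped to zero.  Steady states
by integration extend the horizon geometrically (doubling, 14 extensions
cap) until ‖dx/dt‖∞ < 1e-9 µM/s; that threshold is an operational
definition, the literature gives none.

Analytic steady states of the fundamental subsystem come from the case
analysis of the near-irreversible regime (k_r ≤ 0.1 k_f required for cases
A/B): the closed-form vertices — one of SNAP25/syntaxin exhausted and one of
tSNARE/VAMP2 exhausted, so terminal [FHC] = min over the moiety totals — are
corrected to leading order in k_r/k_f and then refined by a damped Newton
solve of {fluxes = 0, moiety totals fixed} (least-squares steps, residual
backtracking, Levenberg–Marquardt fallback).  Every returned state therefore
satisfies the substitution residual at the actual rate constants, to
~1e-12, rather than only in the irreversible limit.  Case C (comparable
forward/backward rates) additionally seeds from a long-time integration of
the supplied initials.

Classification projects the Jacobian onto the stoichiometric compatibility
class (orthonormal basis of the column space of N, clamped rows zeroed)
before reading eigenvalues — the full-space Jacobian always carries one
zero eigenvalue per conserved moiety, which says nothing about stability.
States are `stable-node` (all real, negative), `stable` (negative real
parts), `saddle` (a positive real part), or `non-hyperbolic` (a real part
within 1e-9·scale of zero).

The preformed-vs-sequential comparison runs both protocols at identical
moiety totals over a fixed assay window (default 100 s): sequential starts
from free proteins; preformed first equilibrates SNAP25 + syntaxin ⇌ tSNARE
alone (to the same steady tolerance) and then adds VAMP2 — and MUNC18,
when modeled, so preincubation happens before the inhibitor can reach free
syntaxin.  A fixed window rather than a deep steady state is deliberate: the
irreversible syntaxin sequestration eventually drains any reversible system
into the same terminal state, and the assays being emulated are
finite-horizon.  Speed is summarized as t90, the first (interpolated)
crossing of 90% of the window-final readout.

## MUNC18 bistability

With the sequestration step irreversible, exact coexisting steady states of
the MUNC18 subsystem require the fusion and FHC\*\*-binding steps to be
irreversible as well; the bistable ground-truth regime therefore sets
k2r = k3r = 0 (their measured dissociation is small).  Steady states are
enumerated by basin sampling: initial conditions are admissible partitions
of the conserved moieties parameterized by (φ, ψ) — φ the fraction of
fusible material pre-assembled as FHC, ψ the fraction of remaining binding
capacity pre-sequestered as Smc — with the four corners of the square always
included and Latin pairs in the interior; FHC\*\*₀ = 0 throughout.
Terminal states are grouped by macroscopic depletion signature rather than
raw distance, because the irreversible chemistry leaves a neutral direction
(the Smc/FHC\*\* split) along which terminal states form a continuum:
**high fusion** = free MUNC18 and free VAMP2 below 1e-3 of their totals,
**low fusion** = free MUNC18 and free tSNARE below 1e-3, anything else
(notably excess MUNC18 beyond the binding capacity) is `other`.  For totals
tSNARE 20 µM and VAMP2 8 µM the two-branch window is
M₀ ∈ (T_tot − V_tot, T_tot] = (12, 20] µM, which the scan reports to within
one grid step; below it only the high branch is feasible, above it the
leftover free MUNC18 ends the bistability.  Counting branches by signature
is what makes the scan's count stable under grid and sample refinement.

## Inverse problem

The observation model is affine, I(t) = a·readout + b + c, valid far below
detector saturation.  The gain a is absorbed into the fitted
fusion-concentration constant K, so the recovered vector is
q = (k1f, k1r, k2f, k2r, K); the background b + c enters the fit as a known
offset (default 0).

The objective is J(q) = ‖F(q) − z‖² + α‖q‖² + P(q) with
α = 1e-6·‖z‖² by default (an L-curve utility is provided), and P a
quadratic hinge on negative entries (weight 1e3).  The search runs on
log-parameters — iterates stay positive and P is inert — inside an optional
admissible box Q_ad.  Phase 1 is steepest descent with a forward-difference
gradient (step 1e-5 in log space) and Armijo backtracking (25 iterations by
default); phase 2 is a quasi-Newton iteration whose Hessian approximation
H = 2JᵀJ comes from the forward-difference Jacobian of the parameter–data
map, with Levenberg damping, a unit trust cap on the log-step, and
active-set reduction on the box faces.  On noiseless synthetic data this
reaches the generating parameters to ~1e-7 relative; the objective history
is monotone by construction (only accepted steps enter it).

Identifiability deserves honesty: a single FHC-only trace constrains the
five parameters very anisotropically.  Profiling shows that fixing k1r at
ten times its true value and refitting the rest reproduces a noiseless
trace to far below a 2% noise floor — a near-structural one-dimensional
degeneracy, along which the maximum-likelihood estimate slides under noise.
Three design choices keep the forward rates recoverable at the few-percent
level anyway: (i) the default ground-truth regime makes assembly
rate-limiting and strongly bimolecular (equal SNAP25 and syntaxin at 2 µM,
whose quadratic depletion breaks the rate-exchange symmetry of a linear
two-step chain), keeps VAMP2 at 4 µM (substantially depleted, so the fusion
rate is not simply slaved to it), and adds a small preformed tSNARE pool
(0.4 µM) that exposes the fusion step at full intensity scale from t = 0;
(ii) the trace window is twice the 95%-of-terminal crossing time, covering
both the rise and an established plateau, sampled at 50 uniform points;
(iii) recovery studies run inside an admissible box spanning a factor 2.5
around a literature-style initial guess (taken at twice the truth), the
constrained formulation that rate recovery from such assays uses in
practice.  Under 2% multiplicative noise this recovers both forward rates
within 15% in ≈95% of seeds; the dissociation rates and their compensating
directions often end on the box faces and should be read as
order-of-magnitude only.

Because scaling all concentrations by λ while scaling bimolecular rates by
1/λ is an exact symmetry of mass action, recovered rates necessarily shift
by ≈1/λ when all assumed initials are mis-stated by the same factor (an
11.1% shift for a −10% error) — no estimator can do better.  The
insensitivity study therefore perturbs each assumed initial independently
and uniformly within ±10% and reports the median forward-rate change
(≈6%), the typical-case sense in which recovery is insensitive to initial
conditions.

Confidence intervals are residual-resampling parametric bootstrap:
residuals of the point fit are resampled with replacement onto the fitted
model, each replicate refit warm-started from the point estimate, and 2.5/
97.5 percentiles taken with the point estimate included in the pool (so
intervals always contain it).  A refit convergence rate below 80% is an
error.  On noiseless data the intervals collapse to the point estimate.

## Robustness sampling

Latin Hypercube designs stratify each parameter's ±delta (default 0.2)
relative interval into n equal strata with exactly one draw per stratum.
Draws come from a counter-based Philox generator keyed by (seed, parameter
index, stratum) and the per-parameter stratum permutation from a generator
keyed by (seed, parameter, n), so designs are bit-reproducible across
platforms and independent of evaluation order.  Zero nominal entries stay
zero (a zero rate is a structural choice, not a samplable one).  Scans
evaluate terminal fusion, t90, the paired protocol comparison, or the
number of stable MUNC18 branches per row, recording per-row failures
without aborting.

## Synthetic data

`ground_truth` fixes three documented regimes: `default` (the recovery
regime above, K = 2), `near-irreversible` (dissociation 1e-4 of
association; the min-rule regime), and `bistable-munc18` (tSNARE 20,
VAMP2 8, MUNC18 16 µM inside the verified window).  `generate_trace`
integrates, observes, and applies multiplicative Gaussian noise
(1 + ε), ε ~ N(0, sd²) — fluorescence noise scales with signal — seeded and
fully described by the trace metadata, which suffices to regenerate a trace
bit-identically.  What the generator does not emulate: photobleaching,
detector saturation, correlated noise, baseline drift, or lot-to-lot
variation in protein activity.  Passing recovery tests on these traces
demonstrates the estimator's correctness and statistical behavior under
the stated noise model, not performance on raw instrument output.

## Problem sizes

The test suite and the acceptance script use: 100 Latin-Hypercube draws per
model variant for conservation audits; 20 random initial-condition sets for
the min-rule; 50 random Case-A instances for the analytic/numeric
cross-check; 100 draws per protocol comparison; 20 noise seeds for the
noisy-recovery study; 10 starts for local uniqueness; 10 replicates for the
insensitivity study; a 14-point MUNC18 grid with 6 basin samples; and the
full 2000 × 5 design for the Latin-Hypercube checks.  The bootstrap
coverage test is scaled down (4 replicates × 19 resamples, coverage pooled
across parameters).

## Known limitations

* The reverse rates k1r, k2r are weakly identified from FHC-only traces
  (see the degeneracy discussion); their reported values lean on the
  admissible box.
* Analytic cases A/B refuse clearly reversible regimes (k_r > 0.1 k_f)
  rather than returning closed forms outside their derivation.
* The bistability count is by depletion signature; it deliberately does not
  resolve the neutral continuum inside a branch.
* No stochastic (Gillespie) simulation and no spatial reaction–diffusion
  form; Ca²⁺ spike trains are not modeled (single rectangular pulse only).
* SBML export is not provided; the YAML network schema is the interchange
  format.
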