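# snarekin

Mass-action modeling, rate-parameter recovery and stability analysis of
SNARE-mediated vesicle fusion (exocytosis).

Exocytosis releases vesicle contents through membrane fusion driven by the
SNARE proteins: SNAP25 and syntaxin on the target membrane assemble into the
binary t-SNARE acceptor complex, which zippers with vesicular VAMP2 into the
four-helical core complex (FHC) that executes fusion.  The core chemistry is

```
SNAP25 + syntaxin  <->  tSNARE          (k1f, k1r)
tSNARE + VAMP2     <->  FHC             (k2f, k2r)
```

regulated by complexin (clamps FHC), Ca²⁺-loaded synaptotagmin (activates
tSNARE and FHC) and MUNC18 (binds FHC into fusion-competent FHC\*\* but also
irreversibly sequesters closed-conformation syntaxin as Smc).  `snarekin`
builds these systems as mass-action ODE networks (d**x**/dt = N·**v**(**x**)
with exact integer stoichiometry N and conserved moieties from its left null
space), integrates them with a stiff solver, and provides:

* **Inverse problem** — recover q = (k1f, k1r, k2f, k2r, K) from a
  fluorescence fusion trace I(t) = a·([FHC]+[FHC\*]+[FHC\*\*]) + b + c by
  minimizing the Tikhonov-regularized energy
  J(q) = ‖F(q) − z‖² + α‖q‖² + P(q) over an admissible parameter box,
  with steepest descent followed by a quasi-Newton phase (Gauss–Newton
  Hessian H = 2JᵀJ), plus residual-bootstrap 95% confidence intervals.
* **Stability analysis** — closed-form steady states of the fundamental
  subsystem (terminal fusion equals the least available moiety in the
  near-irreversible regime; with preformed tSNARE,
  [FHC]∞ = min(T₀ + min(S₀, X₀), V₀)), eigenvalue classification on the
  stoichiometric compatibility class, and preformed-vs-sequential mixing
  protocol comparison.
* **MUNC18 bistability** — basin-sampled steady states of the MUNC18
  subsystem; at intermediate initial MUNC18 the terminal fusion level is
  bistable (a high branch with free MUNC18 and VAMP2 depleted, a low branch
  with free MUNC18 and tSNARE depleted).
* **Robustness** — platform-stable Latin Hypercube rate designs and batch
  outcome scans.
* **Synthetic data** — documented ground-truth regimes and seeded noisy
  fluorescence traces standing in for in-vitro assays (none are deposited).

## Worked example

```python
import numpy as np
import snarekin as sk

# 1. terminal fusion follows the min-rule
variant = sk.fundamental_subsystem()
rates = variant.network.rates_from_mapping(
    {"k1f": 0.7, "k1r": 7e-5, "k2f": 0.4, "k2r": 4e-5})
initials = {"SNAP25": 1.0, "syntaxin": 2.0, "VAMP2": 3.0}
ss = sk.steady_state_by_integration(variant, rates, initials,
                                    sk.SimulationConfig(t_end=500.0))
pred = sk.fusion_level_predictor(initials)
print(f"terminal [FHC] = {ss['FHC']:.4f} uM "
      f"(min-rule prediction {pred.predicted_fhc_infinity:.1f} uM)")

# 2. recover rate constants from a noisy synthetic fluorescence trace
truth = sk.ground_truth("default")
trace = sk.generate_trace(truth, n_points=50, noise_sd_rel=0.02, seed=4)
guess = 2 * truth.params.values
reg = sk.RegularizationConfig(init_guess=guess,
                              bounds=tuple((g/2.5, g*2.5) for g in guess))
result = sk.fit(trace, truth.initials, reg)
for name, est, tv in zip(result.q_hat.names, result.q_hat.values,
                         truth.params.values):
    print(f"  {name}: estimated {est:.4f}  (truth {tv})")

# 3. MUNC18 dose controls mono- vs bistability of the fusion level
scan = sk.bistability_scan(np.linspace(2, 28, 14), ic_samples=6, seed=1)
print(f"bistable window: {scan.window[0]:.0f}-{scan.window[1]:.0f} uM MUNC18")
```

prints

```
terminal [FHC] = 0.9999 uM (min-rule prediction 1.0 uM)
  k1f: estimated 0.2412  (truth 0.25)
  k1r: estimated 0.0400  (truth 0.05)
  k2f: estimated 0.3018  (truth 0.3)
  k2r: estimated 0.0400  (truth 0.05)
  K: estimated 1.9825  (truth 2.0)
bistable window: 14-20 uM MUNC18
```

The SNARE subsystem with dissociation rates four orders below association
converts the scarcest component completely (1 µM of SNAP25 here); a 2%-noise
trace of 50 points pins the forward rates within a few percent while the
weakly identified dissociation rates settle at their admissible-box edge;
and MUNC18 between roughly 14 and 20 µM (for 20 µM preformed tSNARE and
8 µM VAMP2) supports two stable fusion outcomes.

A command-line interface mirrors the library:

```sh
snarekin simulate --out traj.csv
snarekin fit --trace trace.csv --config fit.yaml --out report.json
snarekin bistability --m0-min 2 --m0-max 28 --steps 14 --seed 1 --out scan.json
snarekin lhs --n 2000 --delta 0.2 --seed 1 --out design.csv
snarekin make-fixtures --out-dir fixtures --seed 0
```

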