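# Methods

`hmatch` implements Bayes linear emulation and iterative history matching for
deterministic simulators, and bundles a kinetic model of hormonal crosstalk in
a single Arabidopsis root cell as its flagship case study.  This note records
the statistical model, the numerical choices, and the limits of what the
bundled tests demonstrate.

## The statistical model

### Linking a simulator to reality

An observation `z` of a real quantity `y` is modelled as `z = y + e` with
unbiased observation error `e`, and the simulator `f` at its best input `x*`
as `y = f(x*) + ε`, where `ε` is the model discrepancy — the acknowledged gap
between the simulator at its best and the real system.  Both enter every
comparison only through their variances; the combined standard deviation is
`σ = sqrt(Var(ε) + Var(e))`.  When only a combined σ can be elicited (the
usual case for qualitative trend data) the whole variance is stored in a
single combined slot and flagged as such.

Qualitative trends are encoded on the natural-log scale.  An "Up" trend
meaning "an increase of between 20% and ten fold" is the log-symmetric
interval `z ± 3σ` with `z = (ln 10 + ln 1.2)/2 ≈ 1.24` and
`σ = (ln 10 − ln 1.2)/6 ≈ 0.35`; "Down" is its mirror image; "No change"
uses `z = 0`, `σ = 0.061`.  (The quoted ±40% band for "No change" would give
σ ≈ 0.112 on the natural log; the printed 0.061 is retained as the ground
truth and the inconsistency simply noted.)  Absolute concentration targets of
"0.24 plus or minus an order of magnitude" are placed at `z = ln 0.24` with
`3σ = ln 10`: the only reading under which that interval is symmetric on the
log scale like all the others.

### Bayes linear emulation

Each scalar output is emulated as

    f_i(x) = Σ_j β_ij g_ij(x_A) + u_i(x_A) + w_i(x)

with active inputs `x_A`, a polynomial basis `g_ij`, a weakly stationary
Gaussian process `u_i` with squared-exponential covariance
`σ_u² exp(−‖x−x′‖²/θ²)` over the active coordinates only, and a nugget `w_i`
(white noise, variance `σ_w²`) standing in for the inactive inputs.  Beliefs
are adjusted against the training vector `D_i` by the Bayes linear update
(adjusted expectation and variance); no distributional assumptions beyond
second moments are made.

Choices that matter, with defaults:

* **Scaled space.**  All inputs are affinely mapped to `[−1, 1]`; distances,
  correlation lengths and designs live there.
* **θ = 0.35** (scaled).  Appropriate when a third-order polynomial carries
  the large-scale structure, leaving a smooth high-order residual; no
  maximum-likelihood tuning is attempted by default, as the gain is modest
  when the polynomial fits well.  Per-output override available.
* **Coefficients.**  Default is the vague-prior limit, implemented in the
  universal-kriging / generalised-least-squares form (numerically stable, and
  makes the regression surface equal its least-squares fit).  A fully
  specified β with `Var(β) = 0` is supported for the 1-D worked examples.
* **Residual variance.**  `σ_c² = σ_u² + σ_w²` is set to the squared residual
  standard error of the regression fit; `σ_w² = p·σ_c²` with nugget
  proportion `p` between 0.05 (default) and 0.1, checked by diagnostics.  The
  crosstalk study uses `p = 0.1`.
* **Active inputs** are chosen by forward-then-backward stepwise selection of
  first-order terms under AIC.  The basis is then the complete third-order
  polynomial in the active inputs pruned by the same criterion — backward
  elimination when the full basis is small enough to refit repeatedly
  (≤ min(n/2, 80) terms), greedy forward selection otherwise.  Two safeguards
  matter at moderate run counts: the small-sample-corrected AIC (AICc) is
  used throughout, and no more than n/5 regression terms may be selected, so
  the residual degrees of freedom (and hence the honesty of σ_c²) are
  protected against the heavy selection bias of searching hundreds of
  candidate terms.
* **Cross-covariance and the nugget.**  `Cov(f(x), D_j)` carries only the
  Gaussian-process kernel, so a zero-nugget emulator interpolates its
  training runs exactly with zero variance there, while any `p > 0` forgoes
  exact interpolation — the nugget represents inactive-input variation that a
  revisit of the same active coordinates would not reproduce.
* **Numerical floors.**  A jitter of `1e−10·σ_c²` stabilises the Cholesky
  factorisation; computed variances in `(−1e−10·max(σ_c²,1), 0)` are clamped
  to zero (round-off), anything lower raises (a bug, not round-off).
  Duplicated design points with a zero nugget raise a factorisation error
  naming the offending rows.

Diagnostics follow the prediction-interval convention: an emulator passes on
a held-out design if at least 95% of validation runs fall within
`mean ± 3·sd`.

### Implausibility and history matching

For output `i`, `I_i(x) = |E_D(f_i(x)) − z_i| / sqrt(Var_D(f_i(x)) +
Var(ε_i) + Var(e_i))`.  Outputs are combined by order statistics: the maximum
`I_M`, second maximum `I_2M`, and third maximum `I_3M`, the latter two robust
to one or two emulator failures.  The default cutoff `c = 3` rests on the
three-sigma rule for continuous unimodal distributions (≥ ~95% of mass within
±3σ regardless of skew or tails).  A point is non-implausible when it passes
every configured cutoff of every wave so far — membership in the current
space is a conjunction over waves, so the spaces are nested by construction.

Each wave: design runs over the current space (wave 1: best-of-N maximin
Latin hypercube, bin-centred, Euclidean maximin in scaled space; later waves:
Latin-hypercube batches over the padded bounding box of the cached
non-implausible sample, rejected through chained membership, falling back to
full-space proposals if the box would clip > 1% of cached members); simulate;
drop failed runs (a wave aborts above 20% failures); fit fresh emulators to
this wave's runs only (re-emulation over the shrinking region, not updating
of old emulators); admit outputs whose diagnostics pass into `Q_k` (outputs
are only ever added); impose the wave's cutoffs; estimate the surviving
volume.  Termination: "converged" when every admitted emulator's mean
variance over the surviving sample is below a configured fraction (default
0.1) of that output's combined `σ²`; "empty" when no surviving point can be
found at the search budget.

Volume estimation is uniform Monte Carlo from the initial space with a
nested refinement: when fewer than 50 members turn up, sampling restarts
inside the padded bounding box of the previous wave's surviving cache and the
estimate is rescaled by the box's exact volume fraction.  This resolves
volumes far below `1/n_mc` at the cost of assuming the region stays inside
the box (the padding makes this mild, and the cache is filtered through the
full chain each wave).  The short-circuiting evaluator makes bulk membership
cheap: `I_M ≤ c` fails as soon as one output exceeds `c`, `I_2M` as soon as
two do, `I_3M` as soon as three, so most points are rejected after a couple
of outputs.

Acceptable runs are generated by sampling the final region uniformly,
simulating, and retaining runs whose *simulator-based* implausibility (the
emulator variance term set to zero) passes the certification policy for all
outputs.

## The crosstalk model

Fifteen ODEs describe auxin, cytokinin (CK), ethylene (ET), the POLARIS
transcript and peptide (PLSm, PLSp), an auxin receptor pair (Ra/Ra*), an
ethylene receptor pair (Re/Re*) with downstream kinase pair (CTR1/CTR1*) and
signal X, and three constant feeding pools (IAA, cytokinin, ACC).  The three
receptor pairs are conserved (sums 1, 0.3, 0.3 from the initial conditions),
which is verified symbolically in the tests.  Because the data are
equilibrium trends, only ratios of paired rate constants are identifiable:
eight denominators (k1a, k4, k8, k10, k12, k14, k16, k18a) are fixed to 1 and
the search runs over 23 log-ratios (22 for the k2c = 0 variant, which drops
the PLSp saturation constant along with the saturation factor itself — the
limit k2c → 0 taken with PLSp > 0 held fixed, since the full model is not
continuous at k2c = 0 when PLSp can also vanish).

Scenarios combine genotype (k6 = 0.3 wildtype, 0 for the pls mutant) with
feeding flags entering only through the initial conditions of the constant
pools.  The 18 outputs are ln(Auxin) and ln(CK) in the unfed wildtype
followed by 16 measured trend log-ratios (five Auxin, three PLSm, four ET,
four CK; the mutant-fed-ethylene trend is taken relative to the unfed
mutant, all others relative to the unfed wildtype).

Equilibria are computed with LSODA (analytic Jacobian supplied), rtol 1e−8,
atol 1e−10, integrating to t = 1e4 and verifying
`max |dy/dt| ≤ 1e−8·max(|y|, 1)` per component, extending once to t = 1e5
before declaring failure; failed runs are excluded and counted.  Equilibrium
invariance under the eight-parameter scaling symmetry is the formal check of
the dimension reduction and is asserted in the acceptance tests.

## Problem sizes

The bundled studies run at sizes chosen for a single CPU:

* Wave 1 of the crosstalk match: 1000 training runs, 200 diagnostic runs,
  100 candidate hypercubes for the maximin search, `I_2M ≤ 3.25`,
  `I_3M ≤ 3`, and ≥ 1e5 Monte-Carlo samples for the reported volume.  At
  this size typically 7–15 of the 18 outputs pass diagnostics (the reference
  schedule at 2000 runs admitted 13), and the surviving fraction lands
  within a factor of a few of 2×10⁻¹ — admission of a different output
  subset is the dominant source of run-to-run variation.
* The continued desk-scale match adds two 250-run waves with the reference
  wave-2/3 cutoffs.
* The parameter-recovery study varies five influential inputs (k16a/k16,
  k18, k19/k18a, k1vauxin/k1a, k1veth/k12) around a known generating input,
  with one 80-run wave and 30 diagnostic runs per replicate at `c = 3`.
* `scripts/full_reproduction.py` runs the reference five-wave schedule at
  2000 runs per wave (hours on one CPU) and is the faithful full-scale
  reproduction; the test suite exercises the scaled-down chain only.

## What the synthetic studies do and do not show

The case-study "data" are qualitative trend targets, not new measurements; the parameter-recovery study manufactures observations from a
known input with the same σ budget.  Passing tests therefore demonstrate
that the machinery cuts space correctly, retains true generating inputs, and
reproduces the reference search's scale of volume reduction — not that the
biological model is correct, nor anything about real measurement error
structure (correlated discrepancies across related trends are explicitly out
of scope; every σ here is a scalar).

## Known limitations

* The ODE right-hand sides were reconstructed from the reported constraints
  on the system (the quoted equilibrium, regulatory-limit and conservation
  relations, the ratio structure of the search space, and the companion
  model's interaction network); they reproduce all qualitative behaviour the
  study relies on, but coefficient-level agreement with the original code
  cannot be checked from the text alone.
* Emulator admission near the 95% coverage threshold is noisy at desk-scale
  run counts, so the wave-1 volume varies by a factor of a few between
  seeds.
* The nested volume estimator under-covers regions that escape the cached
  sample's bounding box; the 5% padding and per-wave cache filtering keep
  this small but unquantified.
* The k2c = 0 variant's acceptable region is extremely small (the full-scale
  reference search put it near 2.4×10⁻⁸ of the initial space).  Outputs that
  depend on the same thin mechanism fail their emulators jointly in early
  waves, so the desk-scale variant study keeps conservative third-maximum
  cutoffs for longer before tightening.
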