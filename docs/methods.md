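# Methods

This note documents the models implemented in `tgfswitch`, the conventions
and numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the design decisions taken where the problem was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Core switch model

The core network couples two feedback loops through active TGF-β1 (`T`):
THBS1 is induced by TGF-β1 and activates the latent ligand pool (double
positive loop), while FMOD is repressed by TGF-β1 and sequesters the active
ligand (double negative loop). Production of THBS1 and FMOD follows Hill
kinetics in `T` with exponents `na`, `nb` and constants `Ka`, `Kb` acting on
`T^na`, `T^nb`; TGF-β1 production is the product of an activating THBS1 term
(half-saturation `K1`) and a repressive FMOD term (`K2`); each species
decays linearly.

**Nondimensionalization.** Only the ratios `a/d1`, `b/d2`, `c/d3` are
identifiable from steady-state data, and the stochastic extension assumes a
unit relaxation rate. The package therefore defaults to `d1 = d2 = d3 = 1`,
so `a ≡ a/d1` etc. and dynamic time is measured in protein relaxation
times. All fields remain independently settable for users who want
dimensional rates.

**Steady states.** Substituting the THBS1 and FMOD steady maps into the
TGF-β1 equation gives the scalar self-consistency map `T = f(T)`. Roots are
located by a sign-change scan of `T − f(T)` on a 4,096-point bracketing
grid — half geometric down to 1e-12, half linear — because with
`Ka = 0.016` and `na = 1.6` the map is extremely steep near the origin and
the unstable threshold can sit at `T ≈ 1e-5`. Brackets are refined by
damped Newton iteration with the closed-form derivative (residual tolerance
1e-10); a failed Newton bracket falls back to Brent bisection and the
fallback is recorded on the resulting point. The zero state
`(0, b/d2, 0)` is always included: for `na > 1` the map is superlinear at
the origin, so the zero state is stable whenever `K1, K2 > 0`.

**Stability.** Default mode is the reduced scalar criterion — stable iff
`f'(T) < 1` — with an optional full-Jacobian mode (3×3 eigenvalues). The
two agree whenever the degradation rates are equal; the suite checks this on
random parameter sweeps. Slopes within 1e-6 of 1 are labeled `marginal`
with a warning rather than silently classified, since they indicate fold
vicinity.

**PDL bookkeeping.** Population doubling levels use the conventional
laboratory constant `n = 3.32·(log10 A − log10 B) + X` literally, not
`1/log10(2) = 3.3219...` — a fidelity choice, documented here; the
difference is below 0.06% per doubling.

## Bifurcation analysis

One-parameter scans (`K1`, `K2`, or `γ ≡ c/d3`) assemble a `FixedPointSet`
per grid value; folds are refined by bisection on the fixed-point count
between adjacent grid values (tolerance 1e-8 relative). For the γ fold
specifically there is also a variational method: writing the fixed-point
equation as `T = γ·g(T)` with `g` the γ-independent factor, the nonzero
branch exists iff `γ ≥ T/g(T)` somewhere, so `γ* = min_{T>0} T/g(T)`. The
minimization runs in log-T with a 2,048-point bracketing pass followed by
golden-section refinement; the suite cross-checks it against scan bisection
to 1e-4. With the fitted core parameters and the endogenous constants
`K̃1 = 0.46`, `K̃2 = 0.62`, both methods place the fold near `γ ≈ 0.07`.
Default scan ranges: γ in [1e-3, 10] log-spaced, 512 points; bistability
map 101×101 (reduced grids in tests).

**The K1-scan demonstration rate.** The dose-response fit does not pin
`c/d3`, and the value used for the published K1/K2 scans is not printed.
The package ships `c/d3 = 1.04` for these demonstrations, chosen once so
that with `K2 = 0.62` the K1 fold lies between 14 and 16 *for every* K2 —
then `K1 = 14` sits near the fold (bistable, both basins populated by the
stochastic initial distribution) while at `K1 = 16` no K2 value produces a
bifurcation, and the fold-side phenomenology is reproduced without claiming
the unprinted constant. The zero state is included in stable-state counts;
"high/low" in the binary-switch terminology maps to {upper nonzero stable
state, zero-or-low stable state}.

## Stochastic extension

The stochastic model is deliberately two-stage, mirroring the treatment of
TGF-β1 as a control parameter in the imaging experiment:

1. each path draws `T(0) ~ U(0, T_max)` and relaxes `dT/dt = f(T) − T` by
   forward Euler (`dt = 0.01`) until the per-step change falls below 1e-9;
   the path lands on its basin's fixed point `T̄`;
2. THBS1 and FMOD start at zero and follow mean-reverting OU dynamics
   `dX = (f_X(T̄) − X)dt + σ dB` by Euler–Maruyama for `t_stationary = 20`
   relaxation times (the OU autocorrelation decays as `e^−t`, so 20 units
   far exceed the mixing time); negative excursions are clamped to zero.

TGF-β1 itself carries **no noise** — a naive reading might add noise to all
three equations, but the fluctuating quantities are the two readouts around
their steady maps. With unit relaxation the stationary SD of each
coordinate is `σ/√2`, which the suite verifies at 10,000 paths. Clamping
bias is tracked per path and per coordinate: on the upper branch the THBS1
clamp fraction is below 1%; the FMOD coordinate clamps heavily there by
construction (its upper-branch mean is ~1e-4 against σ = 0.2), which is why
the negligible-bias statement is made for the THBS1 marginal that the
analysis actually uses. Default noise regime: `σ1 = σ2 = 0.2`,
`T_max = 0.2`, 10,000 paths (the alternative printed regime
`σ = 0.05`, `T_max = 1.0` is a config away).

Reproducibility: one `SeedSequence` per ensemble spawns a child stream per
path, so path *i*'s noise is a pure function of `(seed, i)` and enlarging
the ensemble never reshuffles earlier paths.

## Silverman multimodality test

No pre-installed package provides the critical-bandwidth bootstrap, so it
is implemented directly. `h_crit` is the smallest Gaussian-KDE bandwidth at
which the sample's density has at most `k` modes (binary search to 1e-3 of
the sample SD; modes are local maxima on a 512-point grid spanning the
sample range extended by 3 bandwidths). The p-value is the proportion of
`n_boot = 999` smoothed resamples — `scale·(x* + h_crit·ε)` with the
variance-preserving rescale `scale = (1 + h_crit²/s²)^−1/2` — whose KDE at
`h_crit` has more than `k` modes. Calibration runs in the suite show the
test is conservative on unimodal Gaussians and powerful on well-separated
mixtures; tests use `n_boot = 199` to keep runtimes low.

## Steady-state fitting

Both fitters pool replicate-level residuals (each replicate contributes its
own residual, matching the N = 3 design) and run bounded trust-region least
squares (`scipy.optimize.least_squares`, tolerances 1e-14) with positive
scale parameters optimized in log space. Defaults, chosen because the
original procedure reports neither bounds nor starts: amplitudes in
(1e-6, 100], half-saturations in (1e-6, 1e3], Hill exponents in [0.5, 6];
starting values are the maximal observation (amplitudes), the median dose
(half-saturations, with exponent 1 starts), and 1 (exponents).

Identifiability at the study designs: the four-dose design
{0, 0.2, 0.8, 4} exactly identifies the six dose-response parameters, and
noise-free refits recover them to optimizer precision; at CV = 10% the
amplitude medians stay within a few percent while the Hill exponents are
wider (reported in tests, not asserted). The three-PDL design {24, 36, 47}
identifies the endogenous model exactly at zero noise, but because all PDLs
sit far above `Kβ = 5`, the FMOD amplitude β is confounded with `Kβ` (only
`β·Kβ` is well constrained) and its noisy-recovery error is large — an
inherent property of the design, not of the optimizer.

## Reduced TGF-β–VEGF pathway model

The published integrated model (79 reactions, 83 species, 194 parameters)
is not reproducible at desk scale from printed values; this package
implements the stated topology as a reduced network of 25 species and 22
(partly reversible) reactions, with the published counts treated as
metadata. Conventions:

* receptor/ligand steps and kinase cascades are mass action on explicit
  active/inactive pairs, so every pool (SMAD2/3/4, receptors, Raf, MEK,
  ERK, PI3K, Akt, the lumped FMOD transcription factor) is conserved by
  stoichiometry — audited reaction-by-reaction and along trajectories;
* transcription-like steps are Hill; the THBS1 promoter is the **product**
  of SMAD-trimer and AP-1 Hill terms (AND gate), so either input at zero
  silences output;
* SMAD totals default to the measured concentrations
  (SMAD2 0.060 nM, SMAD3 0.38 nM, SMAD4 0.0044 nM); other pools default
  to unit concentrations;
* **trimer formation** (`pSMAD2 + pSMAD3 + SMAD4 → complex`) is linear in
  the limiting SMAD4 pool and saturable in the phospho-SMADs. Strict
  trilinear mass action would make THBS1 output equally sensitive to all
  three pools; with SMAD4 nearly 100-fold below SMAD2 and SMAD3, treating
  the abundant phospho-SMADs as saturating binders is the mechanistically
  natural reduction and yields the observed dominance of SMAD4 knockdown;
* **SMAD7** is expressed as an early pSMAD3 target and inhibits the active
  receptor. Driving SMAD7 from the trimer instead makes the
  trimer-formation sensitivity coefficient cancel between its positive
  (THBS1 gate) and negative (receptor inhibition) paths — the pSMAD3 route
  keeps the negative feedback while leaving the trimer's role as THBS1
  driver intact;
* **Akt crosstalk**: PI3K is activated by the TGF-β receptor (weight 1) and
  the VEGF receptor (weight 0.01), and pAkt represses the FMOD
  transcription step with a Hill-2 term. FMOD turnover (0.075/h) sets the
  recovery clock that separates effective (0/8/24 h) from ineffective
  (32 h) Akt inhibition at the 48-h readout;
* the FMOD transcription factor is a single lumped ERK-activated species —
  its molecular identity is left open by the biology;
* knockdowns scale initial pools (matching siRNA pretreatment before
  stimulation), washout zeroes the external ligand input from its event
  time, and inhibitor events scale a species' *catalytic* activity (its
  appearances in other reactions' rate laws) by the residual fraction —
  scaling its own turnover too would let the pool accumulate and cancel the
  inhibition.

The shipped rate constants were calibrated once against four qualitative
phenotypes — SMAD4-knockdown dominance, the 24-h Akt-inhibition breakpoint,
THBS1's dose sensitivity versus FMOD's robustness to VEGF, and the
equivalence of transient (4-h washout) and sustained stimulation — and are
not fitted to any quantitative time course. The unstimulated network is
pre-equilibrated at build time (500 h) so a zero-dose simulation is flat;
the off state is locally stable against the positive feedback, and the
reference stimulation (dose 1 ≡ the 4 ng/mL condition) ignites the
self-sustaining high-THBS1 state.

**Estimation.** Differential Evolution (`scipy.optimize.differential_evolution`,
rand/1/bin, F = 0.8, CR = 0.9, elitist, polish off) over log-scaled bounds
(default two decades around the shipped values), objective = pooled squared
error between min-max-normalized simulated observables and every replicate
value at the eight sampling times. The published campaign ran 30
independent fits; the suite reproduces the 30-run protocol with reduced
population (popsize 4) and generations (4) per run so the whole campaign
stays inside a desk-scale test budget, and separately verifies recovery
quality with longer runs on two free parameters. Per-generation best
objectives are recorded; elitism makes each trace non-increasing.

**Sensitivity.** `S_y = Δln M / Δln y` with ε = 1% forward differences,
where M is the trapezoidal time-integral of THBS1 under stimulation.
Because the published account is internally ambiguous about whether the
targets are reactions or species, both modes are provided; the default is
reaction mode, matching the labeling of the complex-formation reaction in
the published ranking.

## Synthetic data

Generators are pure functions of (true parameters, design, seed). Default
designs copy the study conditions: doses {0, 0.2, 0.8, 4} ng/mL, PDLs
{24, 36, 47}, the eight sampling times (0, 15, 30, 60, 120 min, 8, 24,
48 h), N = 3 replicates. Replicate noise is multiplicative lognormal with
unit mean by default (expression readouts are positive and their spread
scales with the mean); Gaussian noise is available. The measurement CV is
not reported anywhere in the source analysis; the 5–10% defaults are
package choices, flagged as such.

What the generators do **not** emulate: batch or donor effects, dose-label
measurement error, non-stationary replicate correlation, image segmentation
artifacts in the per-cell intensities, or any sequencing-derived readout.
Passing tests therefore demonstrate correctness of the algorithms under the
assumed statistical structure, not robustness to real-data pathologies.

## Problem sizes and runtimes

The test suite and acceptance script run at the following scales, chosen as
the package's own desk-scale defaults: fixed-point oracles on 1e5-point
grids; γ scans at 64–512 points; ensembles of 10,000 paths for stationary
statistics and modality (Silverman subsamples of 800 cells, 199 bootstrap
resamples); 20-seed recovery studies; a 30-run DE campaign at reduced
population/generations plus a 2-run recovery fit. The acceptance script's
reported quantities (fold γ*, the two plateaus) are deterministic.

## Known limitations

* The reduced pathway model reproduces qualitative orderings, not the
  published parameter values or fitted curves; its rate constants are a
  calibrated illustration of the stated topology.
* No pseudo-arclength continuation or codimension-2 analysis — the reduced
  steady-state problem is scalar and dense scanning suffices.
* The Silverman test uses grid-based mode counting; pathological densities
  with sub-grid mode spacing would need a finer grid.
* Explicit Euler is the default deterministic integrator for consistency
  with the stochastic scheme; an adaptive path (`lsoda`) is available but
  not tuned for stiff parameter regimes beyond the defaults.
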