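# Methods

## Model

The model is the seven-species ODE description of the Rb–E2F
restriction-point switch (identical to BioModels BIOMD0000000318).
States: c-Myc (MC), free E2F (E), cyclin D (CD), cyclin E (CE),
hypo-phosphorylated Rb (R), hyper-phosphorylated Rb (RP) and the
Rb–E2F complex (RE). With Michaelis fractions
f_S = S/(K_S+S), f_M = MC/(K_M+MC), f_E = E/(K_E+E), the kinase terms
g(X) = kP1·CD·X/(K_CD+X) + kP2·CE·X/(K_CE+X) acting on X ∈ {R, RE},
and the phosphatase term h = kDP·RP/(K_RP+RP):

    dMC/dt = kkM·f_S − dMC·MC
    dE/dt  = kkE·f_M·f_E + kb·f_M + g(RE) − dE·E − kRE·R·E
    dCD/dt = kkCD·f_M + kCDS·f_S − dCD·CD
    dCE/dt = kkCE·f_E − dCE·CE
    dR/dt  = kR + h − kRE·R·E − g(R) − dR·R
    dRP/dt = g(R) + g(RE) − h − dRP·RP
    dRE/dt = kRE·R·E − g(RE) − dRE·RE

Phosphorylation of the complex releases free E2F (the +g(RE) term in
dE/dt) and produces RP, conserving mass. All 24 constants are strictly
positive; every one enters at least one term (verified by a dead-
parameter test). Assumptions inherited from the model family: constant
stimulus during a run, no cell growth or division, no explicit p53 or
CDK-inhibitor branches, deterministic mass-action/Michaelis kinetics.

**Units.** Time and concentration are treated as model-native
dimensionless units throughout. Published time-course figures for this
model label axes in minutes and nM, but the rate constants are not
consistent with those units and no conversion is stated anywhere, so
none is invented here.

**Parameter fixtures.** Four named sets ship with the package:
`original` (the published constants) and `opt1`/`opt2`/`opt3`, the
three successive re-calibration rounds. Each round's table lists only
the constants that round re-fitted; the fixtures merge those values
over the original set, since the remaining constants were deliberately
held at their (experimentally grounded) published values. An alias map
(degM→dMC, degRP→dRP, kM→kkM, kE→kkE, kCE→kkCE, kCD→kkCD, …) absorbs
the spelling variants used across sources.

**Default initial condition** is the quiescent state: the stable
equilibrium with lowest E2F at S = 0, found by long-horizon relaxation
from the empty state plus a Newton polish (multistart root search as
fallback). It is fully overridable; no published initial values exist.

**RbTotal** defaults to R + RP (the hypo- plus hyper-phosphorylated
pools, matching a total-Rb immunoblot read against free Rb species);
`ObservableMap.default(include_complex_in_total=True)` adds the Rb
sequestered in the complex, which is itself hypo-phosphorylated — the
literature is ambiguous on whether the complexed pool is counted.

**Integration** uses LSODA with the analytic Jacobian, rtol 1e−8,
atol 1e−10 (configurable); failures raise instead of returning NaNs.
The analytic Jacobian is cross-checked against central finite
differences in the tests.

## Synthetic data

The generator emulates sparse densitometry-style time courses with the
exact statistical structure the GLS objective assumes: additive
homoscedastic Gaussian noise of known constant SD per observable,
independent across observables and times, truncated at zero (negative
concentrations are clipped; this slightly biases points whose signal is
within ~2 SD of zero). Defaults, chosen once:

- observables: CycD, CycE, RbTotal (the three fitted species);
- 10 equispaced times over (0, 30] model-time units, a window covering
  the smooth early-G1 transient;
- stimulus S = 1.5, above the published set's switching threshold
  (S_hi ≈ 1.04): the cell is committed to passing the R-point;
- noise SD = 5% of each observable's noiseless trajectory maximum
  (no published noise magnitude exists); seeded `numpy` Generator,
  identical seed ⇒ identical dataset.

A deliberately considered alternative — extending the horizon to ~300
units so the window includes the E2F/CycE up-switch itself (which at
S = 1.5 fires near t ≈ 200 after a long slow passage) — makes the
least-squares landscape nearly discontinuous in θ, because the switch
time varies explosively with the kinetic constants; multistart fits on
such data stall in poor local minima even at zero noise. That is a real
feature of fitting bistable systems near their threshold, and the
short-window default avoids conflating it with estimator quality.

What the generator does **not** emulate: blot saturation, loading/
transfer normalization, replicate correlation, heteroscedasticity,
cell-population desynchronization. Passing recovery tests on these data
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to real western-blot artefacts.

## Calibration

The objective is J(θ) = Σ_ε Σ_O (y−ym)ᵀ Q (y−ym) with diagonal
non-negative Q per (experiment, observable) block. Weight modes:
`equal` (ω = 1), `exclude` (ω = 0 for named data, which provably
removes their influence), and `scale_reduce` with ω = 1/max(|ym|)²,
the convention that actually equalizes observables of different
magnitude; the bare max(|ym|)² variant (which amplifies large
observables) is available behind a `literal` flag for comparison with
sources that print it that way.

Minimization: bounded trust-region-reflective least squares in log10
parameter space (the natural scale for positive rate constants over a
two-decade box), at most 2000 residual evaluations per start,
convergence tolerances 1e−10. Starts are log-uniform over the bounds
(default 0.1× to 10× nominal, harmonized with the bifurcation scan
range); a failed integration inside a fit contributes the fixed penalty
J = 1e8 rather than aborting the start, and every start's outcome is
kept in the result for audit. During fitting the initial state is the
dataset's recorded one (re-solving the quiescent state of every trial θ
would be ~50× slower and discontinuous in θ).

Round presets free exactly: round 1 — kRE, kkE, kkM, kCDS, kR, KS,
kkCE, KE, KCE, dRP, kkCD, kb (12); round 2 — round 1 minus
{KCE, kkCD, kRE, KS} plus the Rb phosphorylation rates {kP1, kP2}
(10); round 3 — dMC, KM, kkM, dE, kRE, kR, dR, dRP, dCE, KCE, kkCE,
kkCD, kCDS, KS (14).

**Recovery study.** The synthetic-recovery benchmark frees
{kCDS, kkCE, kR, kP1}: the synthesis rates of the three measured
mechanisms plus the dominant Rb phosphorylation rate. This choice
avoids the model's known compensation pairs, which are structurally
unidentifiable from three observables — kkCE/dCE (cyclin E is in
quasi-steady state, so only the ratio is visible), kP1/KE, and
kRE/kkE. Under the default design this set is recovered to ~1e−9
relative from noiseless data (20 starts) and to a few percent median
error at 2% noise.

## Sensitivity ranking

Relative local sensitivities S_p(t) = (∂y_O(t)/∂p)·p/max(|y_O(t)|, ε)
with guard ε = 1e−9 against near-zero observables (guarded points are
logged). Derivatives are central finite differences with relative step
1e−5; the simulations behind them run at tightened tolerances
(rtol 1e−10, atol 1e−12) because the integrator error is amplified by
1/(2h). An independent forward-variational-ODE route
(ds_p/dt = J s_p + ∂f/∂p) cross-checks the differences in the tests.
Sensitivities are evaluated on the same observation design used for
fitting — importance is meant with respect to what is measured.

The ranking score is the root-mean-square aggregate over experiments,
observables, sample times and (globally) Latin-Hypercube samples:

    msqr_p = sqrt( (1/(n_lhs n_ε n_O n_S)) Σ S_p² )

reported with the square root; a rootless variant is a flag (the
induced order is identical). The local rank is exactly the n_lhs = 1
case of the global rank — asserted as an equality in the tests. LHS
sampling is stratified in log space within bounds (default 0.1×–10×
nominal; no published bounds exist), default n_lhs = 200, seed recorded
in the table metadata; ties in the ranking break by canonical parameter
order. LHS samples whose simulations fail are dropped with a logged
count; more than 20% failures is an error.

## Bifurcation analysis

Equilibrium branches versus the stimulus are traced by pseudo-arclength
continuation on (x, S): tangent predictor, Newton corrector in the
hyperplane orthogonal to the tangent, adaptive step (1e−3 initial,
0.02 cap, halving on rejection), stop on leaving the S window
(default [0, 2.5]) or on step underflow (partial branch flagged
`stalled`). Natural-parameter stepping breaks down at saddle-nodes;
arclength rounds them. Stability is the sign of the leading Jacobian
eigenvalue (tolerance 1e−8). Folds are bracketed by reversal of the
tangent's S-component and refined by bisection along the branch to
|ΔS| < 1e−5. Because the choice of seed state could silently miss
disconnected branches, a brute-force sweep (multi-start root finding on
a coarse S grid, log-uniform starts spanning 10⁻⁴–10³ per species plus
chaining from the previous grid point) backs the tracer and spawns new
traces for unmatched equilibria; a 21-point-grid equivalence against
this oracle is part of the test suite. The continuation core is generic
over f(x, s) callbacks and is exercised on cubic normal forms with
closed-form fold locations.

A parameter set is classified `bistable_with_hysteresis` when exactly
two folds with ΔS > 1e−4 lie in the scanned window, else
`monostable_or_transcritical` (the classifier counts folds only and
does not adjudicate transcritical structure). Two-parameter maps re-run
the continuation on a log grid (default 61 points over 0.1×–10×) of a
secondary parameter, recording fold count and S-window; grid failures
are marked, and fold counts outside {0, 2} are warned about as
anomalies.

With the packaged sets this machinery yields: original — folds at
S ≈ 0.132 and 1.042 (width 0.910); opt1 — none; opt2 — folds at
S ≈ 0.058 and 0.108 (width 0.050); opt3 — none.

## Known limitations

- **kRE window.** Scanning kRE with all other constants at their
  published values, bistability persists from below 18 up to 415; the
  apparent upper edge at 415 is where the upper fold crosses S = 2.5,
  i.e. an artefact of the stimulus cap, not a loss of bistability (at
  S_max = 1.5 the same artefact would put the edge near 270). A narrow
  admissible kRE window around the nominal value, as sometimes
  reported for this model, is not reproduced by this implementation
  under any of the packaged baselines; the acceptance scan reports the
  computed edge honestly.
- The classifier's fold-count criterion is blind to bistability whose
  upper fold lies beyond the scanned S range (by design — the window is
  part of the question being asked).
- Identifiability: with three observables, several constants are
  recoverable only in combination (see the compensation pairs above);
  the recovery benchmark quantifies the well-posed subset, not the full
  24-parameter problem.
- The GSA score is a derivative-based screening measure; it is not a
  variance decomposition (no Sobol indices), and rankings at few LHS
  samples fluctuate (seed-stability is tested at a reduced scale).
- Continuation assumes hyperbolic equilibria away from folds; Hopf or
  limit-cycle structure, if induced by exotic parameter sets, is not
  detected.
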