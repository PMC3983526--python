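# rbe2f

Simulation, calibration, sensitivity ranking and bifurcation analysis of
the **Rb–E2F restriction-point switch** — the bistable gene-protein
circuit that commits a mammalian cell to the division cycle.

## The science

During G1, growth-factor stimulation drives the transcription factor
c-Myc, which induces cyclin D and (with E2F itself) E2F. Free E2F is
held in check by the retinoblastoma protein Rb; cyclin D/CDK4-6 and
cyclin E/CDK2 phosphorylate Rb, both free and inside the Rb–E2F
complex, releasing E2F. The positive feedback (E2F autoactivation, the
E2F → CycE → Rb-phosphorylation loop) makes E2F activity a bistable
function of the stimulus *S*: a low-E2F (quiescent) and a high-E2F
(proliferating) steady state coexist over a window
[S<sub>lo</sub>, S<sub>hi</sub>] bounded by two saddle-node
bifurcations. The width of that window is the hysteresis of the
restriction point (R-point): once past it, a cell no longer needs the
stimulus.

The package encodes the standard 7-species ODE model of this switch
(states **MC, E, CD, CE, R, RP, RE**; 24 kinetic constants; identical
to BioModels entry BIOMD0000000318) and provides, as a reusable,
tested pipeline:

- `rbe2f.model` — the vector field, analytic Jacobian, stiff
  simulation, equilibrium finding and observables (CycD, CycE,
  RbTotal = R + RP);
- `rbe2f.synth` — a generator of sparse, noisy synthetic time courses
  (homoscedastic Gaussian noise of known SD) standing in for
  western-blot measurements;
- `rbe2f.calibration` — the generalized-least-squares objective
  J(θ) = Σ<sub>ε</sub> Σ<sub>O</sub> rᵀQr with equal / exclusion /
  magnitude-balancing weights, minimized by bounded trust-region least
  squares from log-uniform multistart, plus the three historical
  free-parameter presets (12, 10 and 14 constants);
- `rbe2f.sensitivity` — relative local sensitivities
  S<sub>p</sub>(t) = (∂y/∂p)·p/|y|, root-mean-square (`msqr`) parameter
  ranking, locally and globally over Latin-Hypercube samples of
  parameter space;
- `rbe2f.bifurcation` — pseudo-arclength continuation of equilibrium
  branches in *S*, saddle-node detection with bisection refinement,
  hysteresis width, two-parameter bistability maps, and a brute-force
  multi-start root-finding sweep as an independent safety net;
- `rbe2f.pipeline` / a `rbe2f` command line — the end-to-end
  synth → fit → rank → bifurcate → classify run with a reproducibility
  manifest.

## Worked example

Classify the four packaged parameter sets — the published constants and
the three re-calibration rounds — by continuation in the stimulus:

```python
import rbe2f as rb

for name in ("original", "opt1", "opt2", "opt3"):
    theta = rb.load_fixture(name)
    branches, folds = rb.model_folds(theta)
    width = rb.hysteresis_width(folds)
    print(f"{name:9s} folds at S = {[round(f.s, 4) for f in folds]}  "
          f"hysteresis width = {width:.4f}  -> {rb.classify_parameter_set(theta)}")
```

prints

```
original  folds at S = [0.132, 1.0416]  hysteresis width = 0.9096  -> bistable_with_hysteresis
opt1      folds at S = []  hysteresis width = 0.0000  -> monostable_or_transcritical
opt2      folds at S = [0.0581, 0.1078]  hysteresis width = 0.0497  -> bistable_with_hysteresis
opt3      folds at S = []  hysteresis width = 0.0000  -> monostable_or_transcritical
```

With the published constants the switch turns on at S ≈ 1.04 and, once
on, stays on until S drops below 0.13 — a wide hysteresis protecting
the proliferation decision. The first re-calibration round (`opt1`)
destroys bistability altogether; the second (`opt2`), which re-fits the
Rb phosphorylation rates and drops the four least sensitive constants,
restores it with a much narrower window (width 0.05 near S ≈ 0.08), a
switch that flips on and off at nearly the same weak stimulus; the
third round (`opt3`) is again monostable.

The same analyses run from the shell:

```sh
rbe2f bifurcate --theta-set original --out-prefix orig
rbe2f synth --theta original --sigma 0.01 --seed 1 --out data.csv
rbe2f fit --round round2 --data data.csv --n-starts 20 --out fit.json
rbe2f gsa --theta-set original --n-lhs 200 --out gsa.csv
rbe2f pipeline --theta-set original --round round1 --out-dir run1/
```

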