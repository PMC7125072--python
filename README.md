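# acetokin

Batch-culture growth and metabolism models for reductive acetogens —
bacteria such as *Blautia hydrogenotrophica* that produce acetate from
hydrogen and CO₂ via the Wood–Ljungdahl pathway
(4 H₂ + 2 CO₂ → CH₃COO⁻ + H⁺ + 2 H₂O).  The package is aimed at
researchers modelling hydrogenotrophic growth in bioreactors or the
gastrointestinal tract who need (i) kinetic model structures that include a
**hydrogen uptake threshold**, (ii) Bayesian MCMC calibration of those
models against batch time-course data, and (iii) the stoichiometric desk
analyses that go with them.

## Models

State variables: hydrogen `H` (mM), acetate `P` (mM), cell dry weight `X`
(g L⁻¹), optionally yeast extract `E` (mM).  All structures share

```
dP/dt = -(1/4) dH/dt          (Wood–Ljungdahl stoichiometry)
dX/dt = -Y dH/dt - k_d X      (yield Y, first-order death k_d)
```

and differ in the hydrogen uptake law:

| structure     | dH/dt                                                         |
|---------------|---------------------------------------------------------------|
| `monod`       | −(μ_max X/Y)·H/(K_H+H)                                        |
| `first_order` | −η X H / Y (linearised Monod, η ≃ μ_max/K_H)                  |
| `t1`          | −η X max(H−H_t, 0) / Y (hard threshold at H_t)                |
| `t2`          | −η X H F(H) / Y, sigmoid gate F = 1/(1+exp(A(T−H)))           |
| `t3`          | reversible Michaelis–Menten: −(X/Y)·(μ_H H/K_H − μ_R P/K_R)/(1+H/K_H+P/K_R) |

The threshold structures encode the observation that acetogens stop
harvesting hydrogen below a minimum concentration (tens of mM for
*B. hydrogenotrophica*).  A two-substrate extension adds first-order growth
on yeast extract with its own yield `Y_E` and an acetate stoichiometry
`b_EP`.  Monod μ_max and K_H are **not separately identifiable** from a
single batch time course — only their ratio is — which the calibration
diagnostics expose as a posterior correlation near 1.

Calibration minimises the sum of normalised squared differences between
model and data (per-point replicate SDs when available, per-variable means
otherwise) with an adaptive-covariance random-walk Metropolis sampler on
log-parameters; the global residual scale is marginalised under a Jeffreys
prior.  Results carry best-fit values, central 95% credible intervals,
split-R̂ convergence flags, posterior log-parameter correlations, and
per-variable R².

## Worked example

```python
import numpy as np
from acetokin import MCMCCalibrator, bernalier_like_scenario, generate_dataset
from acetokin.analysis import t3_steady_state_ratio
from acetokin.literature import T3_BEST_FIT

# synthetic batch culture: hard-threshold (T1) dynamics, 3 replicates, 10% CV
scenario = bernalier_like_scenario(seed=1)
data, truth = generate_dataset(scenario)

cal = MCMCCalibrator("t1", n_iterations=20_000, n_chains=2, random_state=0)
cal.fit(data)
print(cal.result_.summary()[["parameter", "best_fit", "ci95_low", "ci95_high"]])
print("R^2:", {k: round(v, 3) for k, v in cal.r_squared_.items()})
print("steady-state P/H ratio (T3):", round(t3_steady_state_ratio(T3_BEST_FIT), 2))
```

prints (this run)

```
  parameter   best_fit   ci95_low  ci95_high
0       eta   0.000787   0.000760   0.000808
1         Y   0.001398   0.001254   0.001499
2       k_d   0.015125   0.012917   0.016745
3       H_t  90.442802  88.076168  92.454174
R^2: {'H': 0.999, 'P': 0.986, 'X': 0.994}
steady-state P/H ratio (T3): 3.43
```

One realisation of 10% replicate noise puts the fitted threshold at
H_t ≈ 90 mM against a generating value of 86.2 mM (the published best-fit
estimate) — recovery to about 5%, with all other parameters within a few
percent and R² ≥ 0.98 on every observed variable.  The final line is the
acetate:hydrogen ratio at which the reversible (T3) model's net flux
vanishes — cultures evolve toward P ≈ 3.43·H, that model's built-in
hydrogen threshold analogue.

A command-line interface wraps the same functionality:

```
acetokin simulate --model t1 --t-end 300 --out sim/      # H plateaus at 86.2 mM
acetokin generate --scenario bernalier --seed 7 --out data/
acetokin fit --model t1 --data data/dataset.csv --iterations 20000 --out fit/
acetokin analyze --steady-state --ribes 86.2 --stoichiometry
```

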