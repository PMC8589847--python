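# pollenflow

Modelling maize cross-pollination (CP) as a function of distance and the
*field border* (FB) — the unplanted strip (roadway, bare ground) that
typically separates neighbouring fields in small-scale Asian farming
systems.  The package is aimed at coexistence studies of GM and non-GM
maize, where the quantity of interest is the CP rate (the percentage of
grains on a recipient cob fertilised by donor pollen, scored by grain
colour through the xenia effect) and how fast it declines with distance
from the pollen source.

## The models

A dispersal model is the composition of a **kernel** and an **observation
model**.  The kernel γ(s, s′) gives the relative donor pollen density at a
recipient location s whose nearest source is s′; the expected CP grain
count on a cob is λ_s = K·γ(s, s′), with K the average grain number per
cob.  Two kernel families are provided, each a two-branch curve continuous
at a changepoint D:

* **compound exponential** — γ = K_e·exp(−a₁·d*) for d* ≤ D and
  γ = K_e·exp(−a₁·D − a₂·(d*−D)) beyond it;
* **modified Cauchy** — γ = 2β / (π·[β² + d*²]) for d* ≤ D and
  γ = 2β / (π·[β² + D² + c₁·(d*−D)²]) beyond it.

The FB effect multiplies either kernel by exp(−k·√FB), where FB is the
border width in metres; d* is the FB-subtracted distance in the with-FB
variants.  The per-cob count Y_s follows either a Poisson(λ_s) or a
zero-inflated Poisson observation model; in the ZIP case the
Poisson-component weight is tied to distance through the logistic
q_s = 1/(1 + exp(b₁ − b₂·d*)), so structural zeros concentrate far from
the source.  Crossing {Poisson, ZIP} × {exponential, Cauchy} × {FB, no FB}
gives eight model codes: `PExpoN, PExpoB, PCauchyN, PCauchyB, ZExpoN,
ZExpoB, ZCauchyN, ZCauchyB`.

Models are fitted by maximum likelihood (multi-start Nelder–Mead with a
quasi-Newton polish, positivity handled on the log scale) or by adaptive
random-walk Metropolis MCMC; validation uses a grouped threefold
cross-validation in which observations sharing a field design and distance
are split across folds.  Fit quality is reported as AIC, deviance, R² on
grid-level CP rates, the held-out Pearson correlation r, and DIC for the
Bayesian route, with 95% posterior-predictive credible bands for the CP
rate versus distance.

A synthetic-data module generates field experiments with the layouts the
framework was designed around (row spacing 0.75 m, FB widths 0 / 6.75 /
7.5 m, 82 or 91 recipient rows), so the whole pipeline runs without any
field data.

## Worked example

```python
import numpy as np
import pollenflow as pf

# simulate the three-experiment suite (ZExpoB truth, K = 400, 5 cobs/grid)
parts = pf.paper_scale_suite(seed=1)
suite = parts[0].concat(parts[1]).concat(parts[2])

fit = pf.fit_mle(suite, "ZExpoB", seed=1)
print({k: round(v, 4) for k, v in fit.estimates.items()})
print(round(fit.aic, 1), round(fit.r_squared, 3))
```

prints

```
{'K_e': 0.6496, 'a1': 0.5975, 'a2': 0.0503, 'D': 2.8639, 'k': 0.3398,
 'b1': 2.6085, 'b2': 0.0243}
8221.9 0.951
```

i.e. the fitted near-source decline rate a₁ ≈ 0.60 /m, FB rate k ≈ 0.34
/√m and changepoint D ≈ 2.9 m recover the simulation truth (0.6073,
0.3552, 2.8480) to a few percent, and the model explains ~95% of the
variance in grid-level CP rates.  The Bayesian route then quantifies
uncertainty:

```python
post = pf.run_mcmc(suite, "ZExpoB", settings=pf.McmcSettings(seed=1))
band = pf.posterior_predictive_band(post, np.linspace(3, 10, 15),
                                    fb_width=0.0, n_draws=20_000, seed=1)
print(round(float(band.width.mean()), 2))   # mean 95% band width, CP %
```

```
12.92
```

The same pipeline is scriptable from the shell:

```sh
pollenflow simulate --suite --seed 1 --out suite.csv
pollenflow fit --data suite.csv --model ZExpoB --seed 1 --out fit.json
pollenflow crossval --data suite.csv --model ZExpoB --seed 1 --out cv.csv
pollenflow mcmc --data suite.csv --model ZExpoB --seed 1 --out chain.csv
pollenflow predict-band --chain chain.csv --model ZExpoB --fb-width 0 --out band.csv
pollenflow diagnose --data suite.csv --out zero_excess.csv
```

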