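# interpsurv

Interpolation-based parametric survival extrapolation for health-economic
modelling.

Health technology assessment requires survival benefit over a lifetime
horizon, while trial follow-up typically covers only its first fraction. The
standard workaround — fit a handful of parametric models to the observed data
and pick the most plausible extrapolation — fails precisely when none of the
fitted models agrees with external evidence (registry milestones, published
5-/10-year rates) or expert opinion. `interpsurv` inverts the problem:
instead of fitting to data, it solves for the parameters of standard
survival families so that the curve passes **exactly** through
user-specified (time, survival) coordinates, wherever those coordinates come
from.

## The core computation

For a family with survival function S(t; θ), the interpolation conditions
S(t_i; θ) = s_i form an exactly determined system: one point fixes the
exponential rate, two points fix the two-parameter families. The supported
parameterisations are

| family       | S(t)                              | parameters            |
|--------------|-----------------------------------|-----------------------|
| exponential  | exp(−λt)                          | rate λ > 0            |
| Weibull      | exp(−(t/σ)^k)                     | shape k, scale σ > 0  |
| log-logistic | 1 / (1 + (t/σ)^k)                 | shape k, scale σ > 0  |
| log-normal   | 1 − Φ((ln t − μ)/σ)               | meanlog μ, sdlog σ    |
| Gompertz     | exp(−(a/b)(e^{bt} − 1))           | shape b ∈ ℝ, rate a   |

Weibull, log-logistic and log-normal linearise exactly (their transformed
survival is linear in ln t), giving closed-form solutions; the Gompertz shape
b is the unique root of (e^{bt₂} − 1)/(e^{bt₁} − 1) = ln s₂ / ln s₁, found by
bracketed Brent iteration on a strictly increasing ratio. A negative Gompertz
shape yields a survival plateau exp(a/b) — useful, and handled throughout.

Around that core, the package assembles the structures economic models need:
piecewise curves (Kaplan-Meier prefix up to a join time t₀, conditional
parametric tail re-scaled by the anchor S(t₀)), mixture cure models
S(t) = π + (1 − π)S₀(t), a general-population mortality floor
h_adj = max(h_model, h_population) driven by a life table, model averaging,
restricted mean survival time (RMST), and probabilistic sensitivity analysis
in which a variance-covariance matrix estimated from uploaded trial data is
re-centred on the interpolated parameters and sampled (1,000 draws by
default, 2.5/97.5 percentile bands), optionally combined with bootstrap
resampling of the Kaplan-Meier prefix.

## Worked example

Two expert-elicited coordinates — 69.1% survival at 1.46 years and a
pessimistic 10.1% at 4.73 years — determine a Weibull exactly:

```python
from interpsurv import SurvivalInterpolation

res = SurvivalInterpolation([(1.46, 0.691), (4.73, 0.101)],
                            family="weibull", time_unit="years").fit()
print(res.summary())
```

```
Survival interpolation results
==============================================
family:          weibull
time unit:       years
method:          closed_form
converged:       True
max residual:    8.327e-17
----------------------------------------------
parameter             estimate
shape                1.5525404
scale                2.7718353
----------------------------------------------
interpolated points (time, survival, residual):
  (1.46, 0.691)   0.00e+00
  (4.73, 0.101)   8.33e-17
```

The solved curve passes through both coordinates to machine precision
(residuals ≈ 1e−16); `res.rmst(15.0)` reports a restricted mean survival
time of 2.4925 years over a 15-year horizon — the area under the curve, i.e.
undiscounted life-years per patient.

A piecewise extrapolation that keeps the Kaplan-Meier shape until the median
(7.7 months, survival one-half) and then forces a Gompertz tail through a
later follow-up point (17 months, 25%) and an external 5-year rate of 10%:

```python
from interpsurv import build_piecewise

pw = build_piecewise((7.7, 0.5), "gompertz", [(17.0, 0.25), (60.0, 0.10)])
pw.tail.params      # (-0.056393, 0.095777): negative shape, decaying hazard
pw.survival(60.0)   # 0.100000 — the external rate, reproduced exactly
```

The same workflow is scriptable from the shell:

```bash
interpsurv solve --points 1.46:0.691,4.73:0.101 --time-unit years --out out/
interpsurv extrapolate --points 17:0.25,60:0.10 --family gompertz \
    --t0 7.7 --anchor 0.5 --tau 120 --out out/
interpsurv psa --points 7.7:0.5 --family exponential --data events.csv \
    --n-draws 1000 --seed 1 --out out/
```

producing `params.csv`, `curves.csv`, `hazards.csv`, `psa_bands.csv` and a
`report.txt`, each with a provenance header (inputs, seed, version) for
audit trails.

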