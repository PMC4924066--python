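# zinbpanel

Zero-inflated negative binomial (ZINB) models with site-specific random
effects for **unbalanced panels of hourly road-segment crash counts**, plus
the surrounding workflow: a model ladder (Poisson → NB → ZIP → ZINB →
ZINB-RE), Vuong model selection, elasticity post-processing, and a synthetic
segment-hour panel generator.

## Who this is for

Road-safety and injury-epidemiology analysts modelling crash frequency at
refined temporal scales (e.g., one row per road segment per hour, assembled
from Road Weather Information System and traffic-station feeds). At hourly
resolution crash counts are >99% zeros, overdispersed, and serially
correlated within a segment; this package implements the model family built
for exactly that regime.

## The model

Counts n_it (site *i*, hour *t*) follow a two-state mixture. With
probability q_it the segment-hour is in a structurally safe ("virtually
zero-crash") state; otherwise the count is negative binomial with mean
λ_it and overdispersion α:

    P(n_it = 0) = q_it + (1 − q_it) · (1 / (1 + αλ_it))^(1/α)
    P(n_it = y) = (1 − q_it) · Γ(1/α + y) / (Γ(1/α) y!) · u^(1/α) (1 − u)^y,
                  u = (1/α) / (1/α + λ_it)

    λ_it = exp(β_NB · x_NB,it + σ_i),      logit(q_it) = β_z · x_z,it + ψ_i

Site effects σ_i ~ N(0, φ_σ²) and ψ_i ~ N(0, φ_ψ²) capture unobserved
heterogeneity and within-site correlation across the t_i (unequal) repeated
observations per site. The marginal likelihood integrates them out by
Gauss–Hermite quadrature (exact point-mass collapse when a φ is 0), and is
maximized by quasi-Newton with analytic gradients. Zero-inflation is tested
with the Vuong statistic V = m̄·√N / s_m on per-observation log-density
ratios (|V| > 1.96 favors the zero-inflated model; optional AIC/BIC
degrees-of-freedom corrections are available). Elasticities of the expected
count E[n] = (1 − q)λ are β·x̄ for count-state continuous covariates,
1 − e^(−β) for count-state indicators, and observation-averaged for
covariates touching the zero state.

## Worked example

```python
import numpy as np
import zinbpanel as zp

# unbalanced corridor panel from the full reference scenario
sim = zp.generate_panel(zp.SimulationConfig(n_sites=20, horizon_hours=1000, seed=3))
print(sim.panel.n_obs, sim.panel.n_sites, round(float(sim.panel.counts.mean()), 5))
# 11011 20 0.00391

# a compact, well-identified scenario for a fitting demonstration
truth = zp.ZinbReParams(
    beta_nb=np.array([-4.0, 0.08, -0.5, 0.3]),   # const, speed_gap, wet, n_lanes
    beta_z=np.array([0.5, -0.6, 0.35]),          # const, volume, night
    alpha=1.0, phi_sigma=0.4,
)
cfg = zp.SimulationConfig(
    n_sites=30, horizon_hours=300,
    count_design=["speed_gap", "wet", "n_lanes"],
    zero_design=["volume", "night"],
    truth=truth, seed=9,
)
panel = zp.generate_panel(cfg).panel            # 3638 rows, 273 crashes
res = zp.fit(panel, "zinb_re", zp.OptimizerConfig(quad_order=9))
print(round(res.loglik, 2), round(res.params.alpha, 2), round(res.params.phi_sigma, 2))
# -960.12 0.91 0.41
print(res.coef_table().to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
#              state  variable  estimate       se        t        p
#        count-state     const    -4.775    1.067   -4.477    0.000
#        count-state speed_gap     0.064    0.027    2.401    0.016
#        count-state       wet    -0.307    0.254   -1.210    0.226
#        count-state   n_lanes     0.519    0.242    2.142    0.032
#         zero-state     const     0.598    0.547    1.094    0.274
#         zero-state    volume    -0.595    0.473   -1.258    0.208
#         zero-state     night    -0.103    0.441   -0.234    0.815
# dispersion/effects     alpha     0.905    0.585    1.547    0.122
# dispersion/effects phi_sigma     0.407    0.095    4.300    0.000

print(round(zp.pseudo_elasticity_indicator(0.387), 3))
# 0.321
```

The first block draws an unbalanced panel from the full reference scenario
(mean count ≈ 0.004 per segment-hour, >99% zeros). The second fits the
random-effects ZINB to a compact scenario with a higher event rate: every
estimate lands within about one standard error of its generating value
(α = 1, φ_σ = 0.4, slopes as in `truth`), and the site-effect spread φ_σ is
clearly detected (t = 4.3). The last line is the pseudo-elasticity of a
count-state indicator with coefficient 0.387: switching it on raises the
expected hourly crash frequency by 32.1%.

A command-line surface wraps the same pipeline:

```sh
zinbpanel simulate --seed 1 --out panel.csv
zinbpanel fit --panel panel.csv --model zinb_re --out fit
zinbpanel vuong --panel panel.csv --model zinb
zinbpanel elasticity --panel panel.csv --model zinb_re
zinbpanel report --panel panel.csv --seed 1 --out report
```

## Layout

- `src/zinbpanel/data.py` — `PanelDataset` (unbalanced panel container), CSV summary
- `src/zinbpanel/model.py` — pmfs, linear predictors, Gauss–Hermite marginal likelihood
- `src/zinbpanel/fit.py` — the model ladder, SEs, information criteria
- `src/zinbpanel/selection.py` — Vuong test, overdispersion decision
- `src/zinbpanel/elasticity.py` — elasticities / pseudo-elasticities
- `src/zinbpanel/simulate.py` — synthetic segment-hour panel generator
- `src/zinbpanel/io.py`, `cli.py` — CSV/YAML I/O, reports, command line
- `docs/methods.md` — modelling and design notes
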