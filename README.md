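# opscr

Open-population spatial capture–recapture (OPSCR) with cause-specific
mortality and bio-logger (GPS-collar) effects.

## The problem

Telemetry studies must assume that instrumented animals are representative
of the population. Testing that assumption requires survival estimates for
collared *and* non-collared individuals from an independent data source.
Non-invasive genetic sampling (NGS) of a monitored carnivore population
provides exactly that: scat/hair/urine samples identify individuals — with
or without a collar — across many seasons, and dead recoveries report
legal-culling mortality completely while other mortality stays cryptic.

`opscr` implements the joint model that turns such data into
collar-stratified mortality estimates, together with a synthetic-study
generator so the whole pipeline can be validated by simulation and
parameter recovery. It is aimed at quantitative ecologists who want to fit,
probe, or extend this class of model without a bespoke MCMC code base.

## The model

Each (real or data-augmented) individual *i* follows a four-state Markov
chain over monitoring seasons *t*: **1** unborn, **2** alive, **3** dead
from legal culling (occupied for one season), **4** dead from other causes
(absorbing). With inclusion probability ψ, recruitment γ_t and
collar-dependent hazards

    z_i1 ~ dcat(1−ψ, ψ, 0, 0)
    z_it | z_i,t−1 = 2  ~  dcat(0, φ_it, h_it, w_it),   φ = 1 − h − w
    logit(h_it) = h0_t + βhGPS · GPS_it
    logit(w_it) = w0_t + βwGPS · GPS_it

where GPS_it indicates a collar worn in season *t*. Activity centres s_it
live on a discrete habitat grid (20 km cells, including a buffer around the
searched area) with an inhomogeneous point-process start
λ(s) ∝ exp(B·X(s)) and a covariate-weighted Gaussian random walk between
seasons (scale τ). Detection at detector *j* (10 km cells split into 2 km
subdetectors) is half-normal in the AC–detector distance,

    p_ijt = p0_ijt · exp(−D²_ijt / 2σ²),
    y_ijt ~ Binomial(K_j, p_ijt · I(z_it = 2)),

with p0 logit-linear in search effort, road distance, snow cover, a
previous-detection indicator and the collar indicator (βGPS), plus
county-by-season intercepts. Dead recoveries enter as state evidence:
a reported cull forces z = 3 in its season.

Fitting is Metropolis-within-Gibbs: exact single-site Gibbs draws for the
discrete activity centres, forward-filter backward-sampling (or full
forward-algorithm marginalization) for the latent states, adaptive
random-walk Metropolis for the parameters, and half-normal "local
evaluation" to skip far-away zero-count detectors without changing any
observed-count term. The headline outputs are the collar effects βhGPS,
βwGPS and the posterior percentage-point difference in mortality between
non-collared and collared individuals.

## Worked example

```python
import numpy as np
from opscr import (flagship_config, generate_study, prepare_from_synthetic,
                   MCMCConfig, Priors, run_mcmc, derive_collar_contrasts,
                   effect_interval)

config = flagship_config()              # 100x100 km searched area, T=5, M=300
study = generate_study(config, seed=1)  # truth: h0=0.10, w0=0.25,
                                        # beta_h_gps=-0.37, beta_w_gps=-1.08
data = prepare_from_synthetic(study, augment_factor=4.0)
result = run_mcmc(
    data,
    MCMCConfig(n_chains=4, n_iterations=4000, burn_in=1500,
               mode="marginal", seed=1),
    Priors(sigma_max=6.5),
)
print("max Rhat", round(result.max_rhat(), 3))
med, lo, hi = effect_interval(result, "beta_w_gps")
print(f"beta_w_gps median {med:.2f}, 95% CrI ({lo:.2f}, {hi:.2f})")
c = derive_collar_contrasts(result, group=0, season=2)["overall"]["diff_pp"]
print(f"overall mortality difference {c['median']:.1f} pp "
      f"({c['lo']:.1f}; {c['hi']:.1f})")
```

Output from this exact run (~8 minutes on one CPU):

```
max Rhat 1.07
beta_w_gps median -0.57, 95% CrI (-2.91, 1.23)
overall mortality difference 14.8 pp (-5.8; 32.5)
```

The 95% credible intervals cover the generating collar effects (−1.08 and
−0.37) and the generating overall difference (17.7 pp); at this reduced
study size (~110 identified individuals, ~50 ever collared) the intervals
are wide, as expected — point estimates sharpen with study size, coverage
does not.

The same pipeline is scriptable from a shell:

```sh
opscr simulate --preset flagship --seed 1 --out study/
opscr fit --study-dir study/ --seed 1 --chains 4 --iterations 4000 \
          --burn-in 1500 --out fit/
opscr summarize --result-dir fit/ --group 0 --season 2
```

`fit` prints the convergence summary and, because the study directory
carries a truth manifest, an automatic recovery report comparing each
collar effect's CrI with its generating value.

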