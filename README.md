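# mobfit

Fitting fine-scale models of human mobility — a gravity model and four
radiation-model variants — to origin–destination (OD) trip counts that are
only observed between administrative units.

## The problem

Aggregated mobility matrices (for example CDR-derived flows between
districts) are often the only movement data available, yet individual-based
epidemic simulations need flows between much smaller spatial units.  mobfit
fits mechanistic mobility models *at a finer spatial scale than the data*:
the model is evaluated on a population grid (e.g. 20 km, 10 km, 5 km cells
derived from a 1 km population raster), its cell-pair flows are summed over
all cell pairs belonging to each admin-unit OD pair,

    Model_IJ = Σ_{i∈I, j∈J} F_ij ,

and that aggregate is compared with the observed count `Data_IJ` under a
negative binomial likelihood with dispersion `disp`
(var = mean + disp·mean², `disp = 0` is Poisson):

    L = Π_IJ  Γ(D+1/disp) / (D! Γ(1/disp)) · (M/(M+1/disp))^D · ((1/disp)/(M+1/disp))^(1/disp)

with `D = Data_IJ`, `M = Model_IJ`.

Flow kernels:

* **GM** (gravity, directional):
  `F_ij = 10^κ m_i^α m_j^β / (1 + (d_ij/10^γ)^ε)` — offset power-law
  distance kernel, finite at d = 0.
* **GM symmetrised** (for undirected data where outbound and return trips
  cannot be told apart):
  `F_ij = 10^(κ−γε) (m_i^α m_j^β + m_j^α m_i^β) / (1 + (d_ij/10^γ)^ε)`;
  the `10^(κ−γε)` prefactor keeps κ identified when no within-unit counts
  exist (a plain `10^κ` prefactor is available and exhibits the κ–γ ridge).
* **RM1–RM4** (radiation): `F_ij = T_i (m_i+θ) m_j / [(m_i+θ+r_ij+m_j)(m_i+θ+r_ij)]`
  where `r_ij` is the population inside the circle around i through j
  (excluding `m_i`, `m_j`), θ = 0 for RM1/RM2, and the traveller number is
  `T_i = κ·m_i` (RM1, natural-scale κ), `10^κ m_i^α` (RM2), `10^κ m_i`
  (RM3) or `10^κ m_i^α` (RM4).  Radiation models do not predict
  within-unit trips.

Parameters (and `disp`) are estimated by Bayesian MCMC: Latin Hypercube
Sampling of a wide uniform prior box seeds 4 Metropolis chains whose
proposal covariance is adapted during a discarded burn-in window;
convergence is assessed with split-R-hat and summaries use the converged
portion of every chain.  Posterior-predictive utilities compute per-pair
95% credible intervals and their empirical coverage, trip-distance
profiles with power-law fits, and the OD symmetry statistic
`F_ij = 100·(f_ij − f_ji)/max(f_ij, f_ji)`.

Real population rasters and CDR flow matrices are licence-restricted, so a
synthetic-data module generates the two study settings end to end: a
`clustered` scenario (population concentrated in a few dense centres) and a
`dispersed` one (most populated cells hold only a handful of people), with
NB-noised flows drawn from known model parameters.

## Worked example

```python
import mobfit as mf
from mobfit.model import MobilityModel

system, data = mf.scenario_dataset(mf.CLUSTERED, spacing=20_000, seed=11)
model = MobilityModel(data, system, model="GM", symmetrised=True)
res = model.fit(n_iter=20_000, n_chains=4, seed=1)
print(res.summary())
```

prints

```
MobilityModel: GM (symmetrised) on scale '20km'
chains: 4, iterations: 20000, retained from: 10000, converged: True
OD pairs in likelihood: 45
            mean     lo95     hi95    rhat
kappa   -4.91617 -12.5286  2.15619 1.00257
alpha    1.91329 0.955871  2.99043 1.00129
beta    0.684579 0.250763  1.16707 1.00067
gamma    2.21603 0.103434  4.41201 1.00059
epsilon   2.4163   1.9737  2.97012 1.00607
disp     1.41927 0.980443  2.04689 1.00178
loglik  -312.074 -316.094 -309.872     NaN
```

The dataset was simulated from the symmetrised gravity model with
(κ, α, β, γ, ε, disp) = (−4, 1.8, 0.6, 3.5, 2.3, 1.5) on a 169-cell / 10-unit
clustered geography: every true value sits inside its 95% CrI.  The wide κ
and γ intervals are the expected weak identification of the distance-kernel
scale absent within-unit counts; ε (the distance-decay power) and disp (the
over-dispersion) are sharply recovered.  Continuing,

```python
summary = res.posterior_predictive(n_draws=100, seed=2, nb_noise=True)
print("CrI coverage:", round(mf.cri_coverage(data, summary), 3))
prof = mf.distance_profile(data, system, bin_width=10_000)
print("power-law exponent:", round(mf.powerlaw_fit(prof).exponent, 2))
```

prints `CrI coverage: 0.933` (fraction of observed counts inside their 95%
predictive interval) and `power-law exponent: 1.47` (decay of trip
frequency with distance on this synthetic geography).

The same pipeline is scriptable from the shell:

```sh
mobfit synth --preset clustered --spacing 20000 --seed 1 --out runs/synth
mobfit fit --flows runs/synth/flows.csv --system runs/synth/system \
           --model GM --seed 1 --out runs/fit
mobfit predict --flows runs/synth/flows.csv --system runs/synth/system \
               --fit runs/fit --nb-noise --seed 1 --out runs/pred
```

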