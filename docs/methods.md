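# Methods

This note records the models mobfit implements, the numerical and design
choices behind them, what the synthetic data does and does not emulate, and
the known limitations.

## Spatial preprocessing

The geography is a `SpatialSystem`: cells with population-weighted
centroids (planar metres), populations, and an owning administrative unit.
All coordinates are planar; projecting geographic rasters into metres is
the caller's responsibility, which keeps every distance exact and testable.

* **Gridding.** Fine raster pixels are binned into square cells of a given
  spacing.  A cell's population is the sum of its member pixels and its
  centroid the population-weighted pixel mean; cells with zero population
  are dropped.  The grid origin defaults to the raster's minimum corner and
  can be shifted (`origin_offset`), since grid positioning can influence
  estimates.
* **Admin assignment.** Each cell joins the unit contributing the most
  member pixels (a pixel-count area proxy).  Ties break to the smallest
  unit id — arbitrary but deterministic.
* **Unit merging.** A unit that owns no cell at *any* grid scale in use is
  merged into the unit with the nearest population-weighted centroid,
  applied consistently across all scales and repeated to a fixed point, so
  that every scale carries the same unit list.
* **Low-population filter.** Cells with population ≤ threshold (inclusive)
  can be removed to keep fine scales tractable; the default threshold is 0.
  Unit populations are recomputed from the surviving cells and the removed
  cell/population shares are reported.
* **Ring populations.** `r[i, j]` sums the population of all cells k ∉ {i, j}
  with `d(i, k) ≤ d(i, j)`.  Cells at exactly the radius are *included*
  (closed disc), which makes r right-continuous in distance; the convention
  only matters for exactly-tied distances, common on regular grids.
  Computed per row by sort + cumulative sum (O(n² log n)); with integer
  populations the sums are exact.

## Flow kernels

Gravity flows use the offset power-law kernel `1 + (d/10^γ)^ε`, finite at
d = 0, so within-location flows are defined (`F_ii = 10^κ m_i^(α+β)` for the
directional model).  The symmetrised variant sums the two ordered
numerators; its default prefactor `10^(κ−γε)` keeps κ identified when no
within-unit data exist.  With the alternative plain `10^κ` prefactor
(option `scale_factor="kappa"`), and when `10^(γε) ≪ d^ε`, the likelihood
depends on κ and γ only through κ + γε, producing the characteristic ridge
in their joint posterior; the package exposes both conventions and the test
suite demonstrates the ridge.

Radiation flows depend on distance only through the ring population.
θ ≥ 0 inflates the origin population, down-weighting short trips
(RM3/RM4).  RM1's proportionality constant κ is natural-scale and only
bounded below by 0: when the data contain many trips per resident
(year-long observation windows), κ must be free to exceed 1.  Radiation
models define no within-location flow; their diagonal is zero and flagged
excluded.  Symmetrisation is the transpose sum `F_ij + F_ji`, mirroring the
numerator sum of the symmetrised gravity model.

**Aggregation.** At a grid scale, `AdminF[I, J]` sums cell flows over
cells(I) × cells(J) (including cell self-pairs on the diagonal for
gravity).  For diagonal-excluded kernels the admin diagonal is undefined:
within-unit cell pairs are dropped, so total flow is conserved for
cross-unit pairs only.

## Likelihood and masking

The negative binomial log-pmf is evaluated with log-gamma functions in the
size = 1/disp parameterisation; `disp` below 1e-8 switches to the Poisson
branch for numerical stability (the limit is exact as disp → 0).  Masking
rules: observed zeros are ordinary likelihood terms; OD pairs absent from
the input table are *unobserved* and excluded — this one mechanism covers
partially observed matrices and missing diagonals.  Undirected datasets
store the folded count f_ij + f_ji once per unordered pair (origin ≤
destination) and are fitted once per unordered pair against the symmetrised
model flow, avoiding double counting.  Datasets supplied as
proportion-of-nights shares are converted to counts by
`round_half_up(share × residents of origin unit)`; units absent from the
population table or with zero population are dropped.

## Inference

Priors are independent uniform boxes, deliberately wide: α, β, ε ∈ [0, 6],
κ ∈ [−15, 15] (log10; RM1's natural-scale κ ∈ [0, 50]), γ ∈ [0, 7] log10
metres, θ ∈ [0, 10^7] persons, disp ∈ [0, 10].  For the symmetrised gravity
model the exchangeability of α and β under symmetric data is broken by
constraining α > β (proposal rejection); which power "really" belongs to
the origin is not identifiable from undirected data.

Starting points: Latin Hypercube Sampling over the prior box (default 200
points), keeping the highest-likelihood candidates, one per chain (default
4 chains).

Sampler: random-walk Metropolis with a full-covariance Gaussian proposal.
During the burn-in window (default the first half of the chain) the four
chains run in lockstep and share one proposal covariance estimated from
their pooled recent draws, rescaled by 2.38²/d, with a global scale factor
tuned towards the 0.234 acceptance rate that is optimal for multivariate
random-walk proposals.  Pooling matters: the between-chain spread inflates
the proposal exactly along directions where chains still disagree, which is
what merges them across weakly identified ridges (the gravity model's
κ–γ–ε ridge being the motivating case).  Within the same window a small
fraction of proposals are independence moves onto another chain's recent
draw; their acceptance ignores the proposal-density correction, a bias
confined to the discarded window.  When the window closes, a full-covariance
Gaussian mixture (fitted to the pooled second half of the burn-in draws) is
frozen, and the retained phase uses a fixed kernel identical across chains:
90% random-walk proposals (with an occasional symmetric 5× scale
inflation) and 10% independence proposals from the mixture with the exact
Metropolis–Hastings correction.  The independence component supplies
posterior-scale global moves so long flat ridges are traversed at the rate
their mass deserves rather than by diffusion.  A single-chain variant
(`run_chain`) with per-chain adaptation is kept for one-dimensional and
diagnostic work.

Convergence: split-R-hat (each chain halved, classic between/within
variance ratio over the half-chains, clamped below at 1) per parameter,
evaluated on a ladder of candidate truncation points from the end of the
burn-in window to 3/4 of the chain; the earliest truncation with all
R-hat < 1.05 becomes the retained-sample start.  If none passes, the run is
flagged unconverged and the last candidate is reported.  Summaries (means
and equal-tailed 95% CrIs, per parameter and for the log-likelihood) pool
the retained draws of all chains; quantiles use numpy's default linear
interpolation.

Chain lengths are configurable; the package defaults (tens of thousands of
iterations) are sized for the shipped synthetic systems of ~10² cells,
where a 4 × 20k fit takes well under a minute per chain on one CPU.
Million-iteration runs for real country-scale systems are reached by
configuration, not code changes.

## Posterior-predictive analyses

"Simulated flows" are the *expected* flows per posterior parameter draw
(default 100 draws sampled without replacement from the retained pool);
per-pair means and equal-tailed 95% CrIs summarise them.  With
`nb_noise=True` each draw is replaced by an NB realisation at that draw's
dispersion — the correct reference for credible-interval *coverage*
checks, which compare observed counts with the interval bounds.  The
trip-distance profile accumulates trips into right-open distance bins
(default width 10 km) of the OD pair's centroid distance; the power-law fit
is least squares of log10 frequency on log10 bin centre over non-empty
bins, reported as the positive decay exponent with its standard error.
The symmetry statistic `F_ij = 100 (f_ij − f_ji)/max(f_ij, f_ji)` is
computed per unordered pair (skipping pairs with no flow either way) and
summarised by the mean and 95% range of |F|.

## Synthetic data

`synth_population` allocates a fixed total population multinomially over a
mixture of isotropic Gaussian cluster kernels plus a uniform background on
a regular pixel grid — conserving the total exactly and reproducibly per
seed.  `synth_admin` partitions pixels by nearest seed pixel (Voronoi),
seeds sampled population-weighted.  `synth_flows` draws NB counts around a
chosen model's admin-level expected flows via the Gamma–Poisson mixture,
exactly matching the likelihood's parameterisation.

Shipped presets:

* `clustered` — 8 strong centres on a 260 km square, 2 km pixels, 10
  units; at 20 km spacing ≈ 150–170 populated cells with a heavy-tailed
  population distribution.  The total population is sized so that, with
  the preset gravity truth (κ = −4, α = 1.8, β = 0.6, γ = 3.5, ε = 2.3,
  disp = 1.5), simulated admin counts span ~10⁰–10⁴ trips — the magnitude
  regime of year-long CDR matrices, where over-dispersion matters.
* `dispersed` — weak clusters plus a thin background over a 400 km square
  at 5 km pixels, 2.4 million people, 12 units; most populated cells hold
  ≤ 10 people while carrying a small share of the population, so the
  low-population filter removes many cells but little population.  Its
  generator model is RM4 with (κ, α, θ, disp) = (−3.5, 1.3, 2.5·10⁵, 1.8),
  chosen by magnitude analysis so directional admin counts are
  realistically sized.

What the generator does *not* emulate: observation biases of CDR data
(phone ownership and usage heterogeneity), temporal structure, road
networks (distances are Euclidean), or coastline/boundary geometry.
Passing recovery and calibration tests therefore shows the estimator is
correct and well-calibrated *under the model*, not that the model is
adequate for any particular country's data.

## Numerical notes and edge cases

* Model evaluation inside MCMC returns −inf (proposal rejected) for
  non-finite or underflowed flows instead of raising; the public
  `dataset_loglik` raises with the offending pair named.
* Gravity kernels are evaluated as `exp(ε (ln d − γ ln 10))` with the
  diagonal's ln d set to −inf, making the d = 0 kernel exactly 1.
* Radiation flows are monotone decreasing in θ only once
  (m_i + θ)² > r_ij (r_ij + m_j); tests assert the θ → ∞ limit in that
  regime rather than global monotonicity.
* The distance profile uses right-open bins so a distance on a bin edge
  falls in the upper bin; a pair distance exactly at the maximum gets its
  own bin.
* Rounding of proportion-derived counts is half-up (`floor(x + 0.5)`).

## Limitations

* Only Euclidean centroid distances are implemented.
* The likelihood treats OD pairs as independent given the expected flows;
  no spatial correlation of residuals.
* Split-R-hat on heavily ridged posteriors is a necessary but blunt
  diagnostic; for weakly identified parameters (κ, γ without within-unit
  data) the marginal CrIs are prior-dominated and should be read as such.
* GeoTIFF/shapefile ingestion is out of scope; inputs are plain CSV
  rasters already projected to metres.
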