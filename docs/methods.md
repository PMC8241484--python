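# Methods

## Model

`opscr` fits an open-population spatial capture–recapture model for
multi-season individual detection data with dead recoveries. Three coupled
processes define the likelihood.

**Demography.** Every individual — observed or data-augmented — carries a
latent state chain z over seasons: unborn (1), alive (2), dead by legal
culling (3, held for exactly one season so the cull's timing is
identifiable), dead by other causes / long dead (4, absorbing). Inclusion
at the first season has probability ψ; an unborn individual is recruited
with season-specific probability γ_t; an alive individual survives with
φ = 1 − h − w, where the two cause-specific mortality probabilities are
logit-linear in the binary collar covariate (effects βhGPS, βwGPS shared
across groups, intercepts h0_t, w0_t season- and group-specific).
Augmentation treats the population size as the number of augmented
individuals that ever enter the alive state; the covariate of
never-identified individuals is 0, which is exact here because every
collared animal is genetically identified.

The collar covariate is timed self-consistently: the hazards for the
interval (t, t+1] and the detectability in season t both use the collar
status of season t. Collars are fitted to animals already alive in a
season, so letting the covariate of season t modify the transition *into*
t would condition a transition on an assignment that had not yet happened.

**Movement.** Activity centres live on the centres of discrete habitat
cells (default 20 km), covering the searched area plus a buffer so that
movement in and out of the detector array is distinguishable from
mortality. The first-season AC follows an inhomogeneous point process with
log-intensity b_dens·X(c) (X is a density proxy such as den counts); later
seasons follow an isotropic Gaussian random-walk kernel of scale τ
multiplied by the same intensity, normalized by summation over the cells
of the individual's region. Discreteness makes every density proper, which
both the generator and the sampler require; the buffer cells are full
members of the state space. Regions (for sex × region stratification) are
disjoint cell sets and movement never crosses them.

**Detection.** The binomial subdetector design: each 10 km detector is
split into 2 km subdetectors, K_j of which overlap habitat (decided by the
subdetector's centre point); the response y_ijt counts distinct
subdetectors with ≥ 1 detection and is Binomial(K_j, p_ijt·I(z_it = 2))
with the half-normal p_ijt = p0_ijt exp(−D²/2σ²), D the distance from the
AC cell centre to the main-detector centre. p0 is logit-linear in
standardized search-track length, road distance and snow cover
(detector × season), a previous-detection indicator (1 iff the individual
was detected in any *earlier* season — the simplest monotone reading of a
behavioural response), and the collar indicator βGPS; intercepts are
county × season and shared across sexes. σ is shared between collared and
non-collared individuals; the collar acts only on p0.

**Dead recoveries** enter as state evidence, not as AC evidence: a legal
cull in season t forces z_t = 3 (hence alive at t−1, absorbing
afterwards); an other-cause recovery forces z_t = 4 with z_{t−1} = 2.
Detections force z = 2 in their season; a culled individual cannot also be
detected in or after its death season — such data raise a consistency
error during preparation. The admissible-state masks are tightened to
states reachable along legal paths (forward-backward pruning), so the
likelihood and the brute-force path enumeration agree exactly.

## Inference

Metropolis-within-Gibbs with three kinds of moves per iteration:

1. **Activity centres** are updated by exact single-site Gibbs draws over
   the region's cells. The latent state chain is marginalized on the fly
   with forward/backward messages, so the AC update never conditions on a
   particular z. In addition, never-detected individuals get a whole-path
   independence proposal drawn from the movement prior and accepted on the
   ratio of state-marginal detection evidence; without it the buffer
   population decorrelates too slowly and the density slope and
   recruitment parameters inherit the autocorrelation.
2. **Latent states** are drawn by forward-filtering backward-sampling in
   the default `latent` mode (mirroring the categorical formulation), or
   marginalized out of every likelihood by the forward algorithm in
   `marginal` mode. The two modes target the same posterior — checked by a
   Kolmogorov–Smirnov comparison on a small instance — and `marginal` is
   used for the flagship experiments because it mixes faster per
   iteration. In marginal mode the population size is still reported:
   a state chain is drawn by FFBS at each retained iteration.
3. **Parameters** move by adaptive random-walk Metropolis: probabilities
   (ψ, γ_t) on the logit scale with the uniform-prior Jacobian, logit
   intercepts and slopes on their natural scale, σ and τ on the raw scale
   with rejection at their prior bounds. Proposal scales adapt toward ~30%
   acceptance during burn-in only. A proposal making h + w ≥ 1 for any
   collar status realized in the data is rejected outright (the
   categorical transition must stay a simplex).

**Local evaluation.** Zero-count detector terms beyond 6σ of the AC are
skipped (at 6σ the kernel is e^{−18}); any positive count is always
evaluated exactly wherever it falls, so the approximation only drops terms
of order K·p0·e^{−18}. With the radius set to ∞ the likelihood equals the
full evaluation to 1e−12, which the tests assert.

**Priors** (configurable): Normal(0, 2²) on all logit-scale intercepts and
slopes, Uniform(0, 1) on ψ and γ_t, Uniform(0, U) on σ and τ. U for σ
defaults to 10 km and should satisfy buffer ≥ 6·U (a warning otherwise);
the flagship experiments use U = 6.5 km with a 40 km buffer. τ's bound
defaults to 100 km.

**Augmentation size.** The fit augments to 3× the number of genetically
identified individuals by default; after sampling, the run errors if more
than 1% of population-size draws hit the augmentation bound, since the
posterior would then be truncated by an arbitrary implementation constant.

**Convergence** is assessed by the classic split-chain Gelman–Rubin
statistic per parameter (floored at 1; values below 1 arise only from the
finite-sample (n−1)/n correction), with the usual < 1.1 working criterion.

**Checkpointing** is per chain: completed chains' draws are written to the
checkpoint directory and a resumed run skips them, so the resumed result
is bit-identical to an uninterrupted one (chains are independently seeded).

## Synthetic-data generator

`generate_study` composes the three forward processes and emits exactly
what the data-preparation layer consumes: subdetector-level detection
records (jittered within their subdetector), a collar table, dead
recoveries, an ASCII density raster (a smooth sum of Gaussian bumps), and
a truth manifest. Collars are assigned at the start of each season by
topping the collared share of living individuals up to `collar_fraction`
(default duration 2 seasons, never re-fitted), emulating a rolling
capture programme; an optional `collar_recruit_bias` tilts assignment
toward newly recruited individuals for sensitivity studies of non-random
collaring. All legal-culling deaths are recovered; other-cause deaths are
recovered with probability 0.03 (cryptic mortality). Default full-scale
settings mirror the monitoring design the model targets (20/10/2 km grids,
60 km buffer, eight seasons, two regions × two sexes, ~5% of the living
collared); the generating mortality preset is non-collared h = 0.10,
w = 0.25 with collar effects −0.37 (legal) and −1.08 (other) on the logit
scale.

What the generator deliberately does not emulate: genotyping error or
sample-level multiplicity below the subdetector aggregation, age structure
(ages are unknown for NGS-detected individuals, so the model has none),
cause-of-death detail beyond legal/other, and collar loss mid-season.
Passing recovery tests therefore show that the estimator is consistent
with its own assumptions at the simulated scale — not that real data meet
those assumptions.

## The scaled-down flagship experiment

The recovery experiments use a single-group study on a 100 × 100 km
searched area (100 detectors), buffer 40 km, T = 5 seasons, generator
superpopulation M = 300 with ψ = 0.30 and γ_t = 0.12 (≈ 160–180
individuals ever alive), σ = 5 km, τ = 10 km, baseline p0 = 0.12 and ~20%
of living individuals collared. The buffer is 6 × the σ prior bound
(6.5 km) rounded up to whole habitat cells; p0 is higher than the
full-scale default so the reduced detector array still yields informative
detection histories. Fits use 4 chains × 4000 iterations (1500 burn-in) in
marginal mode — chosen so the split-Rhat criterion is met at this problem
size — and augment to 4× the identified individuals (the posterior superpopulation tail reaches ≈3× the identified count in this buffer-heavy design, so the default 3× factor would leave the augmentation check too little margin). The 5-replicate null
calibration uses a further-reduced design (80 × 80 km, T = 4, M = 150,
zero collar effects, 2 chains × 1200 iterations): with wide posteriors the
covers-zero check is insensitive to the short chains.

## Numerical choices

- All normalizations (movement kernels, AC distributions, state
  marginals) are done in log space; categorical draws use the Gumbel
  argmax, so −∞ entries are handled uniformly.
- Nearest-detector and nearest-subdetector assignment breaks exact
  distance ties by the lowest index; grids index 0-based, row-major from
  the lower-left corner.
- Habitat membership of a subdetector is decided by its centre point;
  points on a habitat boundary count as inside (1e−9 km tolerance).
- Covariate standardization constants are computed once over
  detectors × seasons and stored with the grid, so linear predictors are
  reproducible across sessions.
- The retention filter compares exact Euclidean distances via a KD-tree;
  the boundary (distance = radius) is retained.
- Degenerate inputs raise typed errors during preparation
  (`DataConsistencyError`, `ConfigurationError`, `DomainCoverageError`);
  during sampling, constraint violations are −∞ log-likelihoods
  (rejection), never exceptions.

## Known limitations

- ψ and the superpopulation size are weakly identified when the buffer is
  a large fraction of the habitat: undetected augmented individuals can
  sit in the buffer nearly free of detection penalty. The density model
  (shared b_dens·X intensity) is what ties buffer density to the observed
  core, so the posterior on N is honest but wide; the augmentation check
  guards against truncating it.
- Collar-effect posteriors at the scaled-down study size are wide
  (± ~1 logit unit); the flagship checks are coverage checks, and point
  estimates should be interpreted accordingly.
- Within-season timing (a cull before or after an NGS detection in the
  same season) is not modelled; the preparation step rejects data where
  the two collide.
- No goodness-of-fit machinery is provided; the model is validated by
  simulation-based calibration only.
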