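# Methods

`sulaniche` quantifies sex- and year-based niche partitioning in a
central-place-foraging seabird from four data streams: GPS tracks,
blood stable isotopes, morphometrics, and regurgitated diet samples.
This note documents the models, the defaults and why they were chosen,
the numerical details, and what the synthetic-data generators do and do
not emulate.

## Movement

**Trip segmentation.** All fixes within the colony exclusion radius
(default 300 m) are set aside; each maximal run of consecutive
outside-radius fixes bounded by inside-radius fixes is one foraging trip.
Runs that touch the start or end of an individual's record have no
observed departure or return crossing; they are flagged incomplete and
excluded from metrics unless requested. Trip duration is last minus first
fix time; total distance is the sum of great-circle (haversine,
R = 6371.0 km) distances between successive fixes; maximum distance is the
largest fix-to-colony distance. Degree arithmetic is never used for
distance — at 8.5° S a degree of longitude and a degree of latitude differ
by ~1%, and both differ from a kilometre.

**Outlier handling.** A fix is removed when the speeds implied both into
and out of it exceed a ceiling (default 150 km/h, well above sulid flight
speed). The filter is run to a fixed point per individual, so it is
idempotent. Duplicate timestamps keep the first fix and warn; non-monotone
timestamps are a hard error naming the individual.

**Step kinematics.** Movement is reduced to per-step (speed, turn) pairs:
speed over the step following each interior fix, and the absolute angle in
[0, π] between the incoming and outgoing displacement vectors, computed on
a local azimuthal-equidistant (AEQ) plane. All planar work (steps, kernel
densities, overlap) uses the AEQ projection centered on the colony, which
is exact for distances from the center and near-exact for pairwise
distances at foraging-trip scale (< 100 km).

## Behavioral classification

Steps pooled across individuals are clustered into four states by
expectation-maximization on a 4-component bivariate Gaussian mixture in
(speed, turn) space. After convergence the components are relabeled onto a
binary low/high grid — the two lowest speed means form the L-speed pair,
and within each speed pair the lower turn mean is the L-turn member —
giving LL (resting), LH (intensive foraging / intensive searching), HL
(traveling), HH (relocating / extensive searching). Delimiters between the
low and high half-axes are placed at the likelihood-equality crossing of
the adjacent 1-D component marginals, falling back to the midpoint of the
adjacent means when the densities do not cross between them.

Numerical choices:

* Initialization: one binary-grid start (quadrant centroids after an
  axis-wise 1-D 2-means split) plus five k-means++ starts on standardized
  coordinates; the best final log-likelihood wins. The grid start keeps EM
  in the basin the binary clustering intends when turn distributions are
  folded near the axis boundaries.
* Component variances are floored at kinematic noise levels —
  0.25 (km/h)² for speed and 0.02 rad² for turn — because GPS position
  error alone contributes that much jitter to any real step; the floors
  also prevent spike collapse on folded turn distributions.
* Classification is maximum-posterior; ties break toward the lower-index
  state (LL < LH < HL < HH).
* This is a reimplementation of the binary-clustering idea, not a port of
  any reference package; it is validated by ground-truth label recovery on
  simulated trajectories (≥ 95% required on well-separated states; the
  suite observes ~99%).

Per-individual behavior budgets are time-weighted: the fraction of summed
step durations spent in each state.

## Space use

Intensive-foraging (LH) locations per group are smoothed into a kernel
utilization distribution (UD) with an isotropic Gaussian kernel on the AEQ
grid. The bandwidth is the ad hoc (bivariate-normal reference) rule
h = ½(sd_x + sd_y)·n^(−1/6); the default cell size is h/4 (h/2 is the
coarsest allowed) and the grid extends 3h beyond the data. The α-contour
is the smallest set of cells, ranked by density, holding α of the mass;
areas are cell counts × cell area, optionally after removing cells inside
a land (coastline) polygon.

Overlap is the Bhattacharyya affinity BA = Σ √(UD₁·UD₂)·cell area, 0 for
disjoint and 1 for identical distributions. For "overlap at the 50% (or
95%) UD", each UD is first masked to its contour and renormalized (the
masked-renormalized convention; unmasked BA is also available).
Significance uses an individual-level randomization: whole individuals are
shuffled between the two groups (sizes preserved), bandwidths and UDs are
rebuilt per pseudo-group, and pp is the proportion of 1,000 random
overlaps smaller than the observed one; pp < 0.025 or > 0.975 flags a real
difference. Randomizing individuals rather than trips avoids
pseudo-replication of repeated trips by one bird.

## Trophic niche

Isotope values are bivariate (δ¹³C, δ¹⁵N) observations in per mil.

* **Position**: Euclidean distance (ED) between group centroids, tested by
  pooling observations and permuting group labels (sizes preserved).
* **Width (frequentist)**: mean distance to centroid (MDC); |MDC
  difference| is tested by centering each group on its own centroid,
  pooling the residuals, and permuting — the null holds positions fixed
  and asks only about dispersion. The two nulls deliberately match the two
  hypotheses. All permutation p-values use (1 + #{null ≥ observed}) /
  (1 + n_perm), so p is never exactly zero.
* **Width (Bayesian)**: the standard ellipse area SEA_b. The model is
  bivariate normal with a flat prior on the mean and a weakly informative
  inverse-Wishart(df = 3, scale = 10⁻³·I) prior on the covariance; the
  conjugate conditionals are Gibbs-sampled (2 chains × 20,000 iterations,
  burn-in 1,000, thinning 10 → 3,800 retained draws). Per draw the area is
  π·√(λ₁λ₂)·q with λ the covariance eigenvalues and q the χ²₂ quantile at
  the coverage level (5.9915 at 95%; coverage is a parameter, and the
  unscaled standard ellipse — q = 1, ~39% coverage — is available because
  parts of the literature report that convention). A split-chain
  Gelman-Rubin diagnostic on the area draws is recorded and warned about
  above 1.05. Pairwise PP is the fraction of paired draws where one area
  strictly exceeds the other; PP > 0.95 flags a difference.
* **Overlap (probabilistic)**: per paired posterior draw, the probability
  that a point from group a's fitted normal falls inside group b's
  Mahalanobis ellipse at the χ²₂(α) radius, estimated by Monte Carlo
  (default 10⁴ points per draw) and summarized as the median and 2.5/97.5
  percentiles across draws. The measure is directional by construction.
* **Univariate width**: Bartlett's homogeneity-of-variance test per axis,
  used to attribute a bivariate width difference to carbon or nitrogen.

## Morphometrics and diet

The size dimorphism index is SDI = (1 − mean_male/mean_female) × 100,
positive when females are larger (the reverse-dimorphism convention).
The body condition index is built from a PCA on the **correlation** matrix
of standardized culmen, tarsus, and wing chord (the three variables carry
different scales; with it, a PC1 eigenvalue e explains e/3 of the
variance), PC1's sign fixed so all loadings are positive, and body mass
regressed on PC1 by OLS with mass as the response — the standard
condition-index convention, so BCI is mass unexplained by skeletal size.
Residuals sum to zero and are orthogonal to PC1 by construction.

Diet summaries per group: frequency of occurrence (percent of samples
containing a species), percent mass per species (pooled), and per-sample
total mass, item count, and mean prey length — per-sample means are
computed before any cross-sample statistic, since items within one
regurgitate are not independent. Prey-size heterogeneity is the
coefficient of variation of per-sample means.

Generic tests (Spearman matrices, Mann-Whitney U with exact enumeration
for small untied samples, Welch's t, one-/two-way ANOVA with sequential
Type I sums of squares in (sex, year, sex:year) order, Tukey-Kramer
pairwise comparisons, median-centered Levene) delegate to scipy and
statsmodels behind a uniform result type; the two-way decomposition uses
Type I to match the convention of the original analysis environment on a
near-balanced design (Type II is available via an argument).

## Synthetic data

The generators produce datasets with the statistical structure the
analysis assumes, sized like the field campaign (10–32 tracked individuals
and 15–60 trips per season; 9–20 isotope samples per sex × year group;
12–25 regurgitates; 14–25 morphometric records per sex).

* **Tracks**: a semi-Markov multi-state correlated random walk on the AEQ
  plane. Each trip is an outbound traveling leg (HL, persistent heading),
  an area-restricted phase switching among the four states with
  exponential dwell times, and a homing return leg (HL) with a bounded
  (0.08 rad/step) correction toward the colony bearing and a straight
  final approach inside 1 km, which guarantees segmentation closes every
  trip; the search is steered away from the colony inside 3 km. Speeds are
  state-specific truncated normals; turning angles are wrapped normal
  (concentration expressed as mean resultant length), centered at 0 for
  low-turn states and ±2.5 rad (sign per step) for high-turn states —
  strong but incomplete reversals, the signature of area-restricted
  search. Heavier-tailed turning distributions were rejected because their
  tails place steps in the wrong speed × turn quadrant, making the
  generating label unrecoverable from kinematics alone. The default fix
  interval is 10 s (the field tags recorded at 1–10 s; the interval is a
  configuration choice, not a constraint). True state labels ride along
  with each fix for classifier validation.
* **Isotopes**: bivariate normal per sex × year group, defaults at the
  study's group means/SDs (δ¹³C ≈ −15 to −14.7 ‰, δ¹⁵N ≈ 12.0–12.6 ‰,
  n = 9–20).
* **Regurgitates**: per sample, a truncated-Poisson (≥ 1) item count,
  species by weight (anchoveta-only by default), a per-sample mean length
  drawn from the group distribution (defaults female 13.6 ± 0.6 cm, male
  11.6 ± 2.8 cm — the field summaries describe per-sample means, which is
  why the generator draws at that level), item lengths around it with a
  quarter of the between-sample sd, and allometric masses
  (a·length^b, defaults a = 0.0055 g/cm³, b = 3 — a generic clupeoid
  length-weight rule giving ~14 g at 13.6 cm).
* **Morphometrics**: multivariate normal per sex with a common
  off-diagonal correlation (default 0.5) among mass, culmen, tarsus, and
  wing; defaults at the pooled study means (females larger on every axis).

What the generators do **not** emulate: tides, wind, prey fields, dive
behavior, device error (beyond what the outlier filter is tested with),
tissue isotope turnover, digestion bias in regurgitates, or any covariance
between a bird's movement, diet, and isotope values. Passing tests
therefore demonstrate the correctness and calibration of the estimators
under the assumed data-generating structure, not ecological conclusions
about real colonies.

## Problem sizes in the test suite

The suite validates stochastic calibration at reduced but statistically
meaningful sizes: permutation-test uniformity over 200 simulated null
datasets × 299 permutations; overlap-randomization uniformity over 60
datasets × 40 randomizations; classifier recovery on a 20-individual ×
2-trip benchmark (~29,000 steps); SEA_b convergence at n = 10⁴ with the
full chain settings. The full pipeline CLI run on an 8-individual dataset
completes in well under a minute.

## Known limitations

* The EM clusterer assumes Gaussian components in (speed, turn); strongly
  non-Gaussian kinematics (heavy-tailed turns, multimodal flight speeds
  within a state) can misallocate components. The binary-grid
  initialization mitigates but does not eliminate this.
* BA between UDs on mismatched grids is computed by bilinear resampling
  over the intersection extent; with very coarse grids this can differ
  from the same-grid value by up to ~10⁻².
* The Gibbs sampler assumes bivariate normality of isotope groups, as do
  ED/MDC comparisons implicitly through their centroid/dispersion framing.
* Trip metrics treat the GPS record as truth after the single-spike
  filter; systematic drift or gaps are not modeled.
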