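# Methods

## The model

`stcokriging` predicts a primary variable Z_u at an unsampled space–time
point x0 = (s0, t0) from its own observations plus correlated co-variables,
by ordinary cokriging in the space–time domain. Dependence is described by
auto- and cross-semivariograms of the *sum-metric* (Bilonick-type) form

    γ(h_S, h_T) = C0 + C_T·h_T
                + C_S · g_S(h_S; a_S)
                + C_ST · g_ST(h_ST; a_ST),      h_ST = sqrt(h_S² + α·h_T²)

where g is a unit-sill bounded structure (spherical, gaussian or
exponential), C0 is the nugget, C_T the slope of an unbounded linear
temporal part, and α (m²/yr²) the geometric space–time anisotropy ratio
that converts a temporal lag into spatial-equivalent meters. A *single* α
is shared by every model of a fitted set: it defines one space–time metric,
hence one notion of "nearest neighbor" for all variables. By convention
γ(0, 0) = 0 exactly — the nugget applies to any strictly positive lag — and
the kriging matrices use the same convention on their diagonals.

Assumptions: the intrinsic hypothesis per variable pair (increments are
second-order stationary in the space–time lag), spatial isotropy, and — for
the simulator only — joint Gaussianity.

## Empirical variography

Experimental (cross-)semivariograms are computed on a grid of spatial
distance classes crossed with discrete temporal lags:

    γ̂_uv(h_S, h_T) = 1/(2N) · Σ [z_u(s,t) − z_u(s′,t′)]·[z_v(s,t) − z_v(s′,t′)]

over unordered pairs with |s−s′| in the spatial class and ||t−t′| − h_T| ≤
temporal tolerance. Cross-variograms use only *fully co-located* pairs
(both variables measured at both points, co-location resolved with a
0.5 m / 1e-6 yr tolerance). Defaults: 12 equal-width spatial bins from 0 to
half the maximum pairwise distance; temporal lags {0,…,4} yr with tolerance
0.25 yr (annual campaigns make time effectively discrete). Each class
records its pair count and the arithmetic mean of contributing distances;
fitted models are evaluated at those means, which reduces binning bias.
Empty classes are flagged and excluded from fitting, never interpolated.

## Joint fitting

All pair models are fitted *simultaneously* because they share α. The
objective is the weighted least-squares score

    Σ_i  w_i · (γ̂_i − γ(h_Si, h_Ti))²,     w_i = N_i / sqrt(γ̂_i),

summed over every populated class of every pair. For cross-classes with
γ̂ ≤ 0 the weight uses |γ̂| floored at 1e-6 — the literal weight is
undefined there, and magnitude weighting preserves the intent of
down-weighting noisy high-semivariance classes. Temporal slopes C_T are
pre-estimated per pair as the OLS slope of γ̂ against h_T in the first
populated spatial class and held fixed (set `fit_ct=True` to search them
instead), so for p = 4 variables the search space is 5·10 + 1 = 51
parameters.

The optimizer is a real-coded genetic algorithm: tournament selection
(size 3), blend crossover (BLX-0.5, rate 0.9), per-gene Gaussian mutation
(rate 0.1), (μ+λ) survivor truncation with one protected elite, and three
independent restarts keeping the best run. Two numerical choices matter:

- **α is searched on the sqrt scale** (a space–time velocity, m/yr). On
  the quadratic scale the default search box spans ~7 orders of magnitude
  and uniform mutation/crossover steps cannot resolve realistic ratios.
- **The mutation σ anneals geometrically** from 5% to 0.01% of each
  gene's bound width across the run: coarse exploration early, fine
  refinement late. With a fixed σ the search stalls far from the optimum
  (on noise-free self-consistency problems, whose true optimum is 0).

Default bounds: sills in [0, 3·max γ̂] (symmetric for cross pairs), ranges
in [smallest populated lag, 3·largest], α in [0, (max h_S / min h_T)²].
Everything is overridable through `FitBounds`; cross-model sills may be
negative.

## Cokriging

Prediction uses the k nearest samples *per variable* (k-per-variable keeps
every unbiasedness constraint satisfiable; default k = 20) under the
shared metric, with a stable (distance, sample id) tie-break. The
ordinary-cokriging system in semivariogram form couples the Γ matrix of
pairwise (cross-)semivariances with one unbiasedness row per variable
(primary weights sum to 1, each secondary's to 0). The estimate is the
weighted sum of all neighbor values. The kriging variance is computed as
σ² = λᵀb with λ the *full* solution vector (weights and Lagrange
multipliers) and b the full right-hand side; the printed source formula
"λ⁻¹b" is not defined for a vector and the standard form is used instead,
as a deliberate correction.

Pair models fitted independently need not form a valid coregionalization
(`validity_report` diagnoses Cauchy–Schwarz and positive-semidefiniteness
violations per structure — the bundled reference soil-metal set violates
both). Under an invalid set the quadratic form can go negative; negative
variances are floored at zero with a warning rather than raised, since
this is the realistic operating regime of the method. Systems with
condition number above 1e12 raise a singular-system error naming duplicate
points as the likely cause.

Leave-one-out validation deletes, by default, only the primary variable's
value at the held-out point; co-variables measured there stay available
(collocated-cokriging behavior, matching the purpose of testing the
primary prediction). `delete_all_at_point=True` removes everything at the
point. RMSE is computed from the (observed, predicted) pairs; sweep
reports average the kriging variance over the LOOCV points.

Back-transform of log2-scale predictions is the naive 2^ẑ by default; a
lognormal bias correction 2^(ẑ + σ²·ln2/2) is available but off, because
the plain back-transform is the common field practice.

## The synthetic-data generator

`simulate` draws Gaussian realizations under the linear model of
coregionalization: each structure (nugget, spatial, spatiotemporal)
contributes sill_ab·ρ(h) to the covariance, with one PSD sill matrix per
structure and shared ranges/families, so the implied ModelSet is valid by
construction. The covariance is assembled densely (≤ 5000 observations)
with 1e-10 diagonal jitter and factorized by Cholesky.

The default design mirrors a multi-year monitoring campaign: five annual
slices over an 8 km × 8 km area drawn from a fixed pool of 86 sites with
per-year visit counts (86, 45, 48, 55, 48). Revisited sites produce
zero-spatial-lag pairs across years — these carry most of the information
about α. Fresh scatter per year is available with `n_sites=None`. All
variables are co-located per sample by default; heterotopy is opt-in
through per-variable missingness.

The linear temporal term C_T·h_T has no stationary covariance counterpart.
It is emulated by a *single* multivariate Brownian motion in time shared
by all locations (increment covariance 2·C_T·dt): its increments add
exactly C_T_ab·|Δt| to every (cross-)semivariogram, which is precisely the
pure-time part of the sum-metric model (a component with temporal but no
spatial structure is necessarily constant across space). The flip side is
that one realization carries only (number of years − 1) effective degrees
of freedom about C_T, so single-realization C_T estimates scatter widely
no matter how many sites are sampled; C_T recovery is therefore assessed
on replicate means over independent fields of a long (21-year) series.

### What the simulator does not emulate

Real soil-survey features outside the generator: non-Gaussian marginals
(concentration data are log-transformed precisely because they are
skewed), spatial trends and hot spots near sources, preferential sampling,
measurement batch effects, and invalid coregionalizations (the simulator
is valid by construction; the reference soil-metal model set exercises the
invalid regime). Passing tests demonstrate internal correctness and the
qualitative method behavior, not field performance on real campaigns.

## Identifiability and the recovery experiments

Two structural degeneracies of the sum-metric model shape the recovery
harness:

- When sqrt(α)·h_T ≪ a_ST over the observed lags, the ST component is
  effectively time-blind and (C_S, a_S) ↔ (C_ST, a_ST) are exchangeable
  (verified by global optimization: swapped solutions fit noise-free
  surfaces almost perfectly). Recovery targets must use truths whose ST
  component saturates visibly in time.
- When sqrt(α)·h_T spans the whole window for every nonzero lag, the ST
  component degenerates into a "temporal nugget" that absorbs realization
  noise; the α-recovery experiment caps α at (extent / campaign
  duration)² on physical grounds.

A joint 7-parameter fit to one n = 300 realization is not reliably
identifiable (the global optimum of the noisy weighted objective often
sits in a degenerate basin), so `recovery_experiment` pins the structures
absent from the generating spec to zero (`structure_aware_bounds`) — the
analogue of a practitioner fitting only the components the empirical
surface supports — and the two noisy recovery experiments are run at
desk scale with n = 300: a nugget + spherical-S field (fresh scatter) for
sill/range recovery, and a nugget + spherical-ST field on a revisited
60-site network, with the fitting window capped near the structure range,
for α recovery. Problem sizes throughout (n ≤ 1000 simulation points,
GA budgets of 150×1200×3) are desk-scale choices that keep a full
validation run in minutes.

## Numerical conventions

- Co-location tolerance 0.5 m spatially, 1e-6 yr temporally (union-find
  clustering, robust to float noise).
- Pairs beyond the last spatial edge are dropped; a point never pairs with
  itself; unordered pairs are counted once.
- GA restarts use fixed derived seeds (seed + 7919·r), all randomness
  flows from explicit seeds, and runs are bit-reproducible.
- Kriging condition limit 1e12; constraint residual tolerance 1e-8;
  variance floor at 0.
- Workflow stage seeds derive from the global seed by fixed offsets, and
  every run writes a manifest (input hashes, seeds, version, decisions in
  force).

## Known limitations

- No directional spatial variography, no robust variogram estimators, no
  product/product-sum/Gneiting covariances, no kriging with drift, no
  conditional simulation.
- The GA is a global heuristic: on noisy single-realization objectives it
  finds the objective's optimum, which need not be near the generating
  parameters (see identifiability above); fitted parameters deserve the
  same skepticism as any variogram fit.
- Dense simulation limits the generator to ~5000 observations.
- The linear C_T part makes auto-variograms unbounded in time; predictions
  far outside the sampled time window extrapolate accordingly.
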