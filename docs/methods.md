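# Methods

## The model

Reef-year observations of percent hard-coral and macroalgal cover are
classified into six discrete states by joint cover intervals (boundaries at
25% and 50% by default; see below). Transitions between states over one
calendar year are modelled as a time-homogeneous first-order Markov chain on
the states, under four assumptions: reefs are independent realizations of the
same process; the future state depends on the past only through the current
state; transition probabilities are constant over the study period; and all
reefs in a state share the same transition probabilities. None of these are
exactly true of real reefs (larval connectivity couples reefs; size structure
and species composition carry history that cover alone cannot), but they buy
a simple, testable model, and the time-homogeneity assumption is itself
checked by the period homogeneity test.

Counts of transitions out of each source state j are multinomial. With an
independent Dirichlet(α₀, …, α₀) prior on each column of the transition
matrix, the posterior for column j is Dirichlet(n·j + α₀). The default
α₀ = 1 (uniform prior) gives add-one pseudocount posterior means, so
transitions never observed in the data keep positive posterior probability —
the reason a Bayesian treatment is preferred here over bootstrap-based
uncertainty, which would assign an unobserved transition zero spread. The
initial state distribution gets the same conjugate treatment from the state
counts of a baseline year (the latest surveyed year by default, being the
best estimate of current conditions).

Derived statistics (stationary distribution, damping ratio, projected state
and cover trajectories, scenario responses) have no closed-form posteriors;
they are summarized by a generic Monte Carlo algorithm: draw the transition
matrix (column-wise Dirichlet) and the initial distribution from their
posteriors, evaluate the statistic on each of n_rep = 10 000 replicates, and
report the sample mean with 50% and 95% equal-tailed intervals (empirical
percentiles with linear interpolation between order statistics). The
statistic function always receives both draws, keeping one replicate loop for
every statistic.

## State scheme

The default cells, with the convention that the lower category keeps a
shared boundary ("≤25" is [0,25], "25–50" is (25,50], ">50" is (50,100]):

| state | coral | macroalgae |
|-------|-------|------------|
| A | ≤25 | ≤25 |
| B | ≤25 | 25–50 |
| C | ≤50 | >50 |
| D | 25–50 | ≤25 |
| E | 25–50 | 25–50 |
| F | >50 | ≤50 |

These cells partition the feasible triangle {coral ≥ 0, algae ≥ 0,
coral + algae ≤ 100}: cover above 50% in one component forces the other
below 50%, so C and F absorb the whole high-algae and high-coral regions.
The boundaries are configurable for sensitivity analysis, subject to the
partition requirement (upper boundary ≥ 50); the pipeline runs unchanged
under any such scheme. Feasibility is checked with tolerance 1e-6 on the
cover sum to absorb rounding in source tables.

Per-state mean covers (c_i, a_i) for cover projections are averages over the
observations classified into each state. When a state has no observations —
including the counts-only workflow, where no raw covers exist — the centroid
of the state cell clipped to the feasible triangle is used and flagged. The
clipped centroids are computed exactly by polygon intersection (for the
default scheme: A (12.5, 12.5), B (12.5, 37.5), C (16.7, 66.7), D (37.5,
12.5), E (37.5, 37.5), F (66.7, 16.7)). Published region-specific
equilibrium covers depend on the survey-based means, which only exist with
the raw data; with centroid covers the regional *contrast* (Caribbean lower
coral / higher algae at equilibrium than the GBR) is reproduced, but not the
exact percentages, and the package does not claim otherwise.

## Estimation and testing choices

- **MLE fallback.** p̂_ij = n_ij/n·j; a source state never observed gets a
  uniform column and a flag rather than NaNs. The Bayesian path never needs
  the fallback (posteriors are strictly positive).
- **Stationary distribution** is taken from the eigendecomposition (the
  eigenvector for the eigenvalue nearest 1), validated to residual 1e-10,
  with an explicit error when eigenvalue 1 is not simple (reducible chain).
  A 1000-step power-iteration oracle cross-checks it in the tests.
- **Damping ratio** uses λ₁ ≡ 1 exactly (its theoretical value for a
  stochastic matrix) over the numerically computed top eigenvalue, so
  rounding can never produce ρ < 1; |λ₂| below 1e-12 (rank-one chain) maps
  to +∞, and non-finite replicates are excluded from posterior summaries
  with a logged count (an error if they exceed 1% of replicates).
- **Homogeneity LRT.** Zero-count terms contribute nothing (0·log 0 = 0);
  source columns absent from one subset likewise. Degrees of freedom stay at
  (K−1)·m·(m−1) regardless of empty cells, matching the published df = 30
  for two six-state subsets. p-values are reported at full precision. The
  asymptotic χ² approximation is accurate at large counts (empirical size
  0.047 at 3000 pairs per subset in the test suite) but runs a little hot at
  the actual study scale: with 300 pairs per subset the true size is ≈
  0.07–0.09 even under the most favourable homogeneous design (uniform
  matrix, balanced source allocation). Interpreting borderline p-values near
  0.05 at these sample sizes deserves caution; the published regional
  comparison (p ≈ 1e-4) is far from the borderline.
- **Period splitting** assigns a transition pair (t, t+1) to the first
  period iff t+1 ≤ split year (default 2000); the convention is
  configurable.

## Scenario engine

Each column responds to an abstract environmental variable x through a
baseline-category logit with persistence as baseline:
log[p_ij(x)/p_jj(x)] = α_ij + β_ij x, with α_ij = log(p⁰_ij/p⁰_jj) so x = 0
reproduces the current matrix exactly (to machine precision; the transform is
also exactly composable in x). Slope signs come from comparing the coral and
algae intervals of source and destination states: the default *dominance*
rule calls a change positive only when the destination interval lies
entirely at or above the source interval and zero when the intervals overlap
(cells do overlap, e.g. C's coral range contains A's, so a tie-free rule is
needed); a *midpoint* rule (sign of the midpoint difference) is available as
an alternative. The (coral sign, algae sign) pair maps to β ∈ {−1, 0, +1}:
moves gaining coral or losing algae get +1, the reverse −1, diagonal and
offsetting moves 0. Slope magnitude 1 and the x-range [−2, 2] (41 grid
points) are arbitrary conventions — x is unitless and unobserved — so curves
should be read qualitatively. Intercepts are recomputed for every posterior
draw, so scenario bands inherit full posterior uncertainty.

One empirical subtlety: on the Caribbean table the posterior-mean
equilibrium coral cover is not globally monotone in x — it has a shallow
(~0.1 cover point) dip near x ≈ −1.4 before rising steeply for x > 0. The
qualitative response (more coral under favourable conditions, much wider
uncertainty bands at favourable x where high-coral states were rarely
observed) is robust.

## Synthetic data generator

The generator realizes exactly the model's assumptions: per reef, an initial
state from the truth's initial distribution, annual evolution by the true
matrix, and covers drawn uniformly within the generating state's clipped
cell by rejection — so classification round-trips exactly and estimated
matrices can be compared to the truth. Survey designs mimic the two regions:
Caribbean-like (69 reefs, 2–7 observations per reef, median 2) and GBR-like
(55 reefs, 2–11, median 9), both on 1996–2006, with reef-level MPA flags at
the observed regional fractions (65% / 96%). Gaps are modelled as
independent per-year dropout (default rate 0.1) after a reef's first
observed year — real gap structure is irregular and not otherwise modelled.
Preset truths are the add-one posterior means of the packaged count tables,
with their own stationary distributions as initial distributions (both
regions were observed near equilibrium). What passing recovery tests show:
the estimator is consistent for data generated under the model's own
assumptions. What they do not show: robustness to spatial dependence,
reef-level heterogeneity, time-varying probabilities or within-state cover
distributions unlike uniform — none of which the generator emulates.

Well-sampled truth columns are recovered to within multinomial sampling
error; note that a column with ~200 observed transitions still has per-cell
binomial SE up to ~0.03, so element-wise errors of 0.05–0.08 there are
expected fluctuation, not bias (the tests pin < 0.05 recovery on columns
with ≥ 1000 transitions).

## Problem sizes and determinism

Posterior summaries default to n_rep = 10 000 replicates (Monte Carlo SE of
the damping-ratio posterior mean ≈ 0.006 on the Caribbean table); tests use
smaller replicate counts where only structural properties are asserted.
Calibration and power studies in the tests use 1000 simulated datasets of
300 transition pairs per subset (and 3000 pairs where χ² accuracy itself is
the claim). All stochastic operations consume an explicit seeded generator;
the package-wide default seed is 20111102. The CLI writes a manifest (seed,
version, config echo) sufficient to reproduce any run byte-identically.

## Known limitations

- Discretizing the continuous cover distribution into six states loses
  information; results depend (weakly, for moderate changes) on the chosen
  boundaries. The scheme is configurable precisely to let users check this.
- Cover projections treat per-state mean covers as known constants;
  their sampling uncertainty is not propagated.
- Projections are *projections*, not forecasts: they assume the estimated
  transition probabilities persist unchanged.
- The scenario β matrix encodes sign conventions, not measured responses to
  a real covariate; estimating β from environmental data is future work.
- MPA status is consumed as a precomputed boolean; no spatial processing.
- Seasonal timing of surveys within a year is ignored.
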