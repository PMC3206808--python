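# reefmarkov

Bayesian Markov-chain models of transitions between coral reef community
states.

Coral reefs shift between community configurations — coral-dominated,
macroalgae-dominated, and the mixed conditions in between — under fishing,
warming, disease and management. `reefmarkov` models this as a discrete-state
Markov chain: each reef-year observation of percent hard-coral and macroalgal
cover is classified into one of six states A–F (joint cover intervals with
boundaries at 25% and 50%), and annual transitions between states are counted
from consecutive-year surveys of the same reef. The package estimates the
transition probabilities, quantifies their uncertainty, and projects what the
estimated dynamics imply for the long-run composition of a region.

## Model

Let p_ij be the probability that a reef in state j in year t is in state i
in year t+1, collected in a column-stochastic matrix **P** (columns = source
states), so state frequencies evolve as **p**(t+1) = **P p**(t). Transitions
out of each state j are multinomial; with an independent uniform Dirichlet
prior on each column, the posterior for column j is
Dirichlet(n_1j + 1, …, n_mj + 1), giving add-one pseudocount posterior means
and exact posterior sampling. On this foundation the package provides:

- **Projections** of state frequencies and of expected coral/macroalgal cover
  q_c(t) = Σ_i c_i p_i(t) (c_i = mean coral cover of state i), with 50% and
  95% equal-tailed credible intervals from 10 000 joint posterior draws of
  the transition matrix and the initial state distribution.
- **Equilibrium**: the stationary distribution π (right eigenvector of **P**
  for eigenvalue 1) and the damping ratio ρ = 1/|λ₂|, the spectral measure of
  how fast the region approaches equilibrium.
- **Homogeneity tests**: the likelihood-ratio statistic
  L = 2 Σ_k Σ_ij n_ij(k) log[p̂_ij(k)/p̂_ij] with χ² asymptotics on
  (K−1)·m·(m−1) degrees of freedom, for comparing regions, time periods or
  MPA status.
- **Scenarios**: a baseline-category logit perturbation
  log[p_ij(x)/p_jj(x)] = α_ij + β_ij x that slides the transition matrix
  along an abstract environmental axis x (negative = unfavourable to coral,
  positive = favourable), with slope signs derived from the cover geometry of
  each state pair.
- **Synthetic data**: a survey generator realizing the model's assumptions
  (independent reefs, first-order dynamics, homogeneous probabilities) under
  Caribbean-like and GBR-like survey designs, for end-to-end and parameter
  recovery testing.

The package ships the two published regional transition-count tables
(Caribbean: 100 consecutive-year pairs on 69 reefs; Great Barrier Reef: 374
pairs on 55 reefs, both 1996–2006) as loadable datasets.

## Worked example

```python
from reefmarkov import ReefMarkovModel, datasets

res = ReefMarkovModel(datasets.load_caribbean_counts()).fit()
print(res.summary(n_rep=10000, seed=20111102))
```

```
Reef-state Markov chain (columns = source states)
==========================================================
transition pairs: 100   prior alpha: 1.0

Posterior-mean transition matrix:
        A       B       C       D       E       F
A  0.5686  0.4762  0.0909  0.3750  0.3333  0.3333
B  0.2745  0.3333  0.4545  0.0312  0.1667  0.1111
C  0.0588  0.0476  0.1818  0.0312  0.0833  0.1111
D  0.0588  0.0476  0.0909  0.3750  0.2500  0.2222
E  0.0196  0.0476  0.0909  0.0938  0.0833  0.1111
F  0.0196  0.0476  0.0909  0.0938  0.0833  0.1111

Stationary distribution: A=0.470  B=0.262  C=0.064  D=0.109  E=0.047  F=0.047
Equilibrium cover: coral 19.2%, macroalgae 23.9%
Damping ratio: 2.54 (95% CI 1.77, 3.95; 10000 draws)
```

Reading this: a Caribbean reef with low coral and low macroalgae (state A)
stays in A with posterior-mean probability 0.57 and moves to the
macroalgae-heavier state B with probability 0.27; at equilibrium under
constant conditions nearly half of reefs sit in state A and a quarter in B.
The damping ratio of ~2.5 means departures from equilibrium shrink by that
factor per year — the region is within a few years of its long-run
distribution. (Equilibrium cover here uses the geometric centroids of the
state cells as per-state mean covers; supply survey-based `CoverSummary`
estimates for region-specific values.) A homogeneity test of the two regions,

```python
from reefmarkov import lrt_homogeneity
r = lrt_homogeneity([datasets.load_caribbean_counts(), datasets.load_gbr_counts()])
print(r)   # LRT homogeneity: L = 67.5152, df = 30, p = 0.0001036 (...)
```

rejects a shared transition matrix decisively.

A command-line interface mirrors the library
(`reefmarkov classify|count|estimate|project|test|scenario|simulate|run-all`);
`reefmarkov run-all --config analysis.yaml --out-dir out/` runs the full
pipeline and writes a reproducibility manifest.

## Layout

- `src/reefmarkov/states.py` — state scheme, classification, cell geometry
- `src/reefmarkov/surveys.py` — survey I/O, validation, pooling, cover means
- `src/reefmarkov/transitions.py` — transition counting and count-matrix I/O
- `src/reefmarkov/estimation.py` — MLE and Dirichlet-multinomial posterior
- `src/reefmarkov/dynamics.py` — projection, stationary distribution, damping
  ratio, posterior summaries of derived statistics
- `src/reefmarkov/homogeneity.py` — likelihood-ratio homogeneity tests
- `src/reefmarkov/scenarios.py` — baseline-category logit scenario engine
- `src/reefmarkov/synthetic.py` — survey simulator with known truth
- `src/reefmarkov/model.py` — `ReefMarkovModel` / `ReefMarkovResults`
- `src/reefmarkov/cli.py` — command-line pipeline

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
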