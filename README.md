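# phylodisp

Bayesian inference of discrete-geographic history ("discrete phylogeography")
for pathogens: given a time-calibrated phylogeny and the area in which each
sampled pathogen was collected, infer where the outbreak originated, which
dispersal routes carried it, and how many dispersal events occurred — with
first-class support for auditing how strongly those conclusions depend on the
prior model.

## The model

Dispersal among `k` discrete areas along a fixed rooted time tree Ψ is a
continuous-time Markov chain with instantaneous-rate matrix `Q`, built as

```
q_ij = r_ij · δ_ij
```

where `r_ij > 0` is the relative dispersal rate between areas `i` and `j` and
`δ_ij ∈ {0, 1}` is an indicator that switches route `i–j` on or off (BSSVS —
Bayesian stochastic search variable selection). `Q` is rescaled so that the
uniform-weight mean off-diagonal flow equals the average dispersal rate `μ`
(events per unit time); with tree length `T = Σ` branch durations, `μ·T` is
the expected number of dispersal events over the whole history. `Q` may be
symmetric (`K = k(k−1)/2` routes) or asymmetric (`K = k(k−1)`). The posterior

```
P(r, δ, μ | G, Ψ) ∝ P(G | r, δ, μ, Ψ) · P(r) P(δ) P(μ)
```

is sampled by Metropolis–Hastings MCMC, with the likelihood computed by
Felsenstein pruning.

Two prior models are built in, per component:

| component | default | alternative |
|---|---|---|
| routes Δ = Σδ (symmetric) | offset Poisson, λ = ln 2, zero mass below Δ = k−1, irreducible configurations equiprobable given Δ | offset Poisson centred on half the maximum number of routes |
| routes Δ (asymmetric) | Poisson with mean k−1 | Poisson with mean k(k−1)/2 |
| rate μ | Gamma(0.5, T) — implies E[events] = 0.5 for *any* T | exponential with a Gamma(0.5, 0.5) hyperprior on its mean (a K-distribution) — implied event count scales with T |

The default priors encode a surprisingly strong belief — about half a
dispersal event in the entire history, and very sparse route sets for
moderate `k` — which shrinks inferred rates and event counts and inflates
per-route Bayes factors. The package quantifies all of this: stepping-stone
marginal likelihoods and `2 ln BF` model comparison, per-route inclusion
Bayes factors `BF_ij = posterior odds / prior odds` with Kass–Raftery
categories, ancestral-area probabilities and dispersal-event counts from
endpoint-conditioned stochastic mapping (uniformization), and
posterior-predictive adequacy checks.

## Worked example

```python
import numpy as np
from phylodisp.simulate import SimulationScenario, simulate_tree, simulate_history_and_tips
from phylodisp.ctmc import GeoModelParams, build_rate_matrix, n_routes
from phylodisp.model import DiscreteGeographyModel

tree = simulate_tree(SimulationScenario(n_tips=30, k=4, seed=8))
K = n_routes(4, symmetric=True)
truth = GeoModelParams(True, np.ones(K), np.ones(K, int), mu=12.0 / tree.tree_length)
hist, data = simulate_history_and_tips(tree, build_rate_matrix(truth, 4), root_area=0, rng=9)

model = DiscreteGeographyModel(tree, data)          # default priors
res = model.fit(chain_length=20_000, seed=1)
print(res.summary())
```

```
Discrete-geographic dispersal model
================================================================
areas (k):        4    tips: 30    tree length T: 21.51
Q symmetry:       symmetric
routes prior:     default (Poisson lam=0.6931, offset=3)
rate prior:       default
retained samples: 1500
----------------------------------------------------------------
parameter             mean        2.5%       97.5%       ESS
mu                  0.2186     0.08822      0.3827       215
Delta                4.448           3           6       448
----------------------------------------------------------------
top routes by 2lnBF:
  area0 - area3: post_p=0.983 2lnBF=+7.24 (strong)
  area2 - area3: post_p=0.885 2lnBF=+3.17 (positive)
  area1 - area3: post_p=0.701 2lnBF=+0.79 (none)
  area0 - area2: post_p=0.682 2lnBF=+0.61 (none)
  area1 - area2: post_p=0.623 2lnBF=+0.09 (none)
```

The generating rate was `μ = 0.558` (12 expected events); the default-prior
posterior mean is `0.219` — the shrinkage induced by the 0.5-expected-events
prior is visible directly. Refitting with
`DiscreteGeographyModel(tree, data, routes_prior="alternative",
rate_prior="alternative")` recovers a higher rate, and
`model.log_marginal_likelihood()` lets you compare the two prior models by
`2 ln BF`. Downstream summaries hang off the results object:
`res.route_support()`, `res.ancestral_areas()`, `res.event_counts()`,
`res.annotated_newick()` (BEAST-style `[&area_probs=...]` comments), and
`res.posterior_predictive_check()`, which for this dataset reports

```
AdequacyReport(parsimony: obs=8, p=0.12)
AdequacyReport(multinomial: obs=-32.67, p=0.16)
```

i.e. the fitted model adequately reproduces both the phylogenetic clustering
(parsimony score) and the evenness (tipwise multinomial statistic) of the
observed tip areas.

The same workflow is scriptable from the shell: `phylodisp simulate | infer |
marglik | routes-bf | map-history | ppcheck | prior-audit | compare` (see
`phylodisp --help`).

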