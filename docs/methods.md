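# Methods

## Model

Geographic history is a CTMC over the areas `0..k−1` running along a fixed
rooted time tree. The tree is data: branch durations are taken in the tree's
own time units and are never re-estimated. Unscaled rates are
`q'_ij = r_ij δ_ij` (mirrored when the symmetric constraint is on); the
matrix is rescaled by a constant `c` chosen so that

    (1/k) Σ_{i≠j} q_ij = μ,

i.e. the *uniform-weight* mean off-diagonal flow equals the average dispersal
rate. Uniform weights — rather than the stationary distribution of Q — are
used deliberately: indicator configurations that are reducible (possible
under the asymmetric route prior, which imposes no connectivity constraint)
have no unique stationary distribution, and the rescaling must be defined
for every state the sampler can visit. The same convention is used
everywhere (likelihood, simulation, stochastic mapping, event-count
calibration), so `μ·T` is exactly the expected number of simulated events
when all routes are open; this was held fixed across the package and is the
single place a rate-scale convention enters.

Root area frequencies default to uniform `1/k` and are configurable. The
likelihood is Felsenstein pruning with per-node rescaling; a pattern with
probability zero (e.g. a reducible Q that cannot produce the observed areas)
returns `-inf` rather than raising, so Metropolis–Hastings rejection handles
such proposals uniformly. Branch transition matrices are computed in one
pass per likelihood call: a symmetric Q goes through a single `eigh`
decomposition, a general Q through `eig` with a scaling-and-squaring `expm`
fallback when the eigenvector basis is ill-conditioned (condition number
above 1e8); computed probabilities are clipped to [0, 1] and row-normalized,
with closure checked at 1e-10 in tests.

## Priors

**Routes.** The symmetric prior is offset Poisson on Δ = Σδ: zero mass below
Δ = k−1 (the minimum for an irreducible model), Poisson(λ) on the excess,
and all irreducible configurations with the same Δ equiprobable. Because the
Poisson tail above K = k(k−1)/2 is unattainable, the Δ-marginal is truncated
and renormalized, and each configuration's probability divides by the number
of irreducible configurations in its Δ class. That count is computed
exactly: exhaustive enumeration for K ≤ 15, and the classical
connected-labeled-graph recurrence (subtracting graphs whose component
containing vertex 1 is proper) with exact integer arithmetic for larger K;
the two agree on their overlap by test. Default λ = ln 2; the alternative
sets λ so the expected Δ is half the maximum, floored at ln 2 — the floor
binds for k ≤ 4, where the half-maximum target would fall at or below the
irreducibility offset, so for those k the default and alternative symmetric
route priors coincide. Asymmetric: plain Poisson (mean k−1 default, K/2
alternative) over Δ ∈ [0, K] with `C(K, Δ)` equiprobable configurations and
no connectivity constraint.

Some samplers instead weight every configuration by the raw Poisson factor
without the per-class division; both styles are implemented
(`delta_prior_style = "per-delta-count"` (default) or
`"per-configuration"`), both normalized to sum to one over all 2^K
configurations. Note that under the renormalized default at small k the mass
on Δ = k−1 exceeds the untruncated value e^{−ln 2} = 0.5 (e.g. 0.59 at
k = 3); no specific mass value is asserted anywhere.

A consequence used by the route Bayes factors: by exchangeability of routes
under area relabeling, the prior inclusion probability of any single route
is `Σ_Δ p(Δ)·Δ/K`, computed exactly from the Δ marginal — no enumeration
needed at large k. Under the truncated alternative asymmetric prior this is
slightly below 1/2 (the Poisson mass above K is clipped); the deviation is
below 0.01 for k ≥ 4.

**Rate.** Default: μ ~ Gamma(0.5, rate T). Mixing with N | μ ~ Poisson(μT)
gives the marginal N ~ NegativeBinomial(size 0.5, p = 1/2) — independent of
T, with E[N] = 0.5, P(N = 0) = 2^{−1/2}, and 97.5% quantile 3. Alternative:
μ | m ~ Exponential(mean m), m ~ Gamma(0.5, 0.5). The hyper-mean m is kept
as an explicit latent parameter in the MCMC state rather than evaluating the
marginal K-distribution density (which involves Bessel functions); the
marginal moments are verified by simulation instead. The implied event-count
prior under the alternative is computed by Monte Carlo over m using the
analytic geometric mixture N | m ~ NB(1, 1/(1+mT)), and is tagged with its
per-entry MC standard error.

**Relative rates.** i.i.d. Exponential(1). The main construction leaves this
prior unpinned; Exponential(1) is the conventional discrete-phylogeography
choice, it is configurable (`rr_rate`), and the resolved value is echoed
into every trace header and report.

## MCMC

Single-site Metropolis–Hastings with five move types: log-scale multiplier
moves on μ, on one randomly chosen r_ij, and on m (alternative rate prior
only); a single-indicator flip; and a paired flip exchanging one open and
one closed route (preserving Δ, which helps mixing across equal-Δ
configurations). Multiplier windows are tuned toward 30% acceptance in
blocks of 50 iterations during burn-in only, then frozen, so retained
samples come from a fixed kernel. Initialization: δ all-ones (always
irreducible), r = 1, m = 1, μ drawn from its prior — a guaranteed finite
starting density. When k = 2 with the symmetric constraint the single route
can never close (irreducibility), so indicator moves are disabled rather
than warning about structurally impossible proposals. The sampler targets
`prior × likelihood^β` for β ∈ [0, 1]; β = 0 runs need no data and are used
both for prior-calibration tests and as the first stepping stone.
Determinism: one `numpy` Generator seeded from the settings drives
everything; identical settings give bit-identical traces.

Effective sample sizes come from arviz's autocorrelation-based estimator;
a constant column is reported as ESS = N with a warning (the autocorrelation
time is undefined there).

## Marginal likelihoods and Bayes factors

Stepping-stone sampling with β on the Beta(0.3, 1)-quantile ladder
(default 32 stones, denser near the prior where the integrand moves
fastest), each stone an independent MCMC run. The estimator accumulates
`log E_{β_j}[L^{β_{j+1}−β_j}]` in log-sum-exp form; uncertainty is a
batch-means SE per stone combined in quadrature, or the SD across
independent replicate ladders when several are run. Stepping-stone is the
only estimator offered (harmonic-mean estimators are unstable). Validation
is against closed forms: a conjugate Gamma–Poisson marginal with exactly
sampled power posteriors, and 1-D quadrature on a two-tip, μ-only model.

Route support: `BF_ij = [p̂/(1−p̂)] / [q/(1−q)]` with p̂ the retained-sample
inclusion frequency and q the exact prior inclusion probability; p̂ ∈ {0, 1}
is replaced by the chain's 1/(N+1) resolution bound and flagged. Categories
follow the conventional 2lnBF thresholds (2/6/10). Model-level comparison is
`2(logML_a − logML_b)`.

## Stochastic mapping

Histories are drawn exactly: pruning down-pass, joint node-state up-pass,
then each branch filled by endpoint-conditioned uniformization — the number
of dominated-process jumps is drawn from its exact conditional pmf
(truncated when the accumulated series reaches 1 − 1e-10 of the endpoint
probability), states follow the discrete bridge through powers of
`R = I + Q/Ω` with `Ω = max_i |q_ii|`, jump times are uniform order
statistics, and virtual jumps are discarded. A forward-simulate-and-reject
sampler is retained purely as a test oracle. One history is drawn per
retained posterior sample, so ancestral-area tables and event counts
marginalize over the posterior of Q. Because the tree is fixed by design,
comparisons of node summaries between prior models are same-tree
comparisons; the shared-node fraction is 1 by construction and the
changed-MAP fraction can be read directly from the two ancestral-area
tables.

## Posterior-predictive adequacy

Replicates are simulated forward from evenly thinned posterior draws; the
observed data are scored by (i) the unit-cost Sankoff/Fitch parsimony score
and (ii) the tipwise multinomial statistic `Σ n_a ln(n_a/n)`. These two are
the package's own choice of a standard discrete-character adequacy pair —
one sensitive to phylogenetic clustering of areas, one to area-frequency
evenness — and the statistic set is pluggable. The p-value is the doubled
minimum tail probability, capped at 1, with `p < 0.05` flagged inadequate.

## Synthetic data

The generator emulates small published discrete-phylogeography datasets:
Yule (crown-conditioned, no root stem — the dispersal process runs over
exactly the branches that carry probability) or Kingman coalescent trees,
a true Q from chosen (r, δ, μ), and exact Gillespie simulation of the
dispersal history root-to-tips. Ground-truth histories are kept so that
stochastic mapping can be validated against the realized truth, not only
against tips. The benchmark suite crosses k ∈ {3, 5, 8} and 20–50 tips with
sparse (Δ = k−1, a uniform random spanning tree) versus dense (complete)
route sets and low (0.5 expected events — matching the default prior) versus
high (3k expected events) rates, so that default-versus-alternative
contrasts are informative by construction. What the generator does *not*
emulate: phylogenetic uncertainty (trees are known exactly), sampling bias
across areas, time-stratified sampling, and rate variation across branches —
so passing tests demonstrate correctness of the inference machinery under
the model, not robustness of the model to real-data violations.

## Problem sizes and numerical choices

Routine validation runs use deliberately modest sizes chosen as a desk-scale
testing regime: 20–50 tips, k ≤ 5, chains of 10–20k iterations (thinned
to hundreds–thousands of samples), 16–32 stepping stones of a few thousand
iterations, and 20 replicates for coverage checks; Monte Carlo comparisons
use 3-SE bands. Degenerate inputs are handled explicitly: T = 0 trees parse
but are rejected for inference; Δ = 0 yields a flagged zero matrix; zero
branch durations contribute identity transition matrices; zero-probability
endpoint pairs raise in the mapper and return `-inf` in the likelihood.

## Known limitations

- No joint inference of the phylogeny; the tree is an input.
- No GLM-style covariate parameterization of Q and no branch-specific rates.
- Asymmetric irreducible-configuration counting is enumerative and limited
  to small K (the asymmetric priors do not require it).
- Event counts are sampling-based (stochastic mapping), not analytic
  expected Markov-jump counts.
- The printed reference table of published log marginal likelihoods is used
  only for arithmetic cross-checks of the 2lnBF machinery; one of its 14
  rows is internally inconsistent beyond input rounding and the
  corresponding check documents that discrepancy rather than hiding it.
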