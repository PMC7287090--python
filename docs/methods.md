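# Methods

## Model

Gene-level de novo mutation (DNM) counts from parent-offspring trios are
modeled per gene *i*, trait *k*, and variant-annotation category *c*
(e.g. loss-of-function, damaging missense). Under the null the count is
Poisson with mean 2·N_k·μ_ic (N_k trios; μ_ic the per-gene per-category
mutation rate, expected mutations per chromosome per generation). In a
risk gene the Poisson mean is multiplied by a latent relative risk
γ ~ Gamma(γ̄_kc·β_kc, β_kc), giving the compound marginal

  P(x) = NegBin(x; r = γ̄β, p = β/(β + 2Nμ)),

used in closed form everywhere (validated against arbitrary-precision
quadrature to ~1e-12 in the test suite). Multi-category evidence is the
product over categories; the two traits may have different numbers of
categories.

Jointly, each gene belongs to one of four models — risk for neither
trait (H0), trait 1 only (H1), trait 2 only (H2), or both (H3) — with
mixture weights derived from the single-trait risk proportions π_k^S and
the shared proportion π3:

  π1 = π1^S − π3, π2 = π2^S − π3, π0 = 1 − (π1^S + π2^S − π3),

so π3 ∈ [0, min(π1^S, π2^S)]. Per-gene posterior probabilities PP0..PP3
are the prior-weighted normalized likelihoods; PP1+PP3 and PP2+PP3
summarize per-trait evidence; the gene-level genetic overlap is
gO = 100%·π3/(π1+π2+π3), a monotone function of π3.

Note that the four-weight mixture with π3 = 0 is *not* the product of two
independent single-trait mixtures (it encodes mutual exclusivity of the
two risk states), so per-trait posteriors agree with the two-component
single-trait model only approximately in that regime — in practice to a
correlation above 0.9999 and identical calls at the usual thresholds.

## Estimation

**Single-trait hyperparameters** (π^S, γ̄_c, β_c per trait) are fitted by
bounded multi-start MAP (L-BFGS-B on logit π and log γ̄, log β; default 8
restarts) of the two-component mixture likelihood. The implied priors are
uniform on π and log-uniform on γ̄ and β within the bounds
π ∈ [1e-5, 0.5], γ̄ ∈ [1, 1e4], β ∈ [0.01, 100]. Point hyperparameters
are all the joint stage consumes, so the MAP route is the default; an
optional random-walk Metropolis refinement (2 chains, split-R̂ reported)
provides posterior means and convergence diagnostics. The dispersion β
can be fixed via `fix_dispersion` for users who prefer an external tie
between β and γ̄; by default it is estimated jointly. Degenerate data are
flagged rather than rejected: a likelihood flat in π (e.g. γ̄ → 1, where
the mixture is unidentifiable) triggers a `flat_likelihood` flag and the
estimate is pinned to the most parsimonious value (the lower π bound),
with `pi_at_lower_bound` recorded.

**Shared proportion π3.** With single-trait hyperparameters held fixed,
π3 is the only free parameter. The default estimator evaluates the
posterior ∝ prior(π3)·L(π3) on a 2001-point grid over the support,
normalizes by trapezoid rule, and reads the mode (argmax) and 95%
equal-tailed credible interval from the grid CDF — deterministic 1-D
quadrature, exact to grid resolution, with no sampling noise in tests. A
random-walk Metropolis sampler on logit-rescaled π3 (defaults: 2 chains ×
10,000 steps, 1,000 kept per chain from the second half, split-R̂
diagnostic, warning above 1.1) mirrors the MCMC route; its mode is read
from a Silverman-bandwidth Gaussian KDE on a 2001-point grid. The two
estimators agree within 0.005 on the same data in the test suite. The
prior on π3 is uniform on the support by default; a Beta(a, b) rescaled
to the support is available in the config. The gO point estimate and CI
are the π3 mode and CI pushed through gO(π3) (monotone, so quantiles
transform exactly).

All likelihood arithmetic is in log space with log-sum-exp
normalization; counts up to 50 at 2Nμ down to 1e-10 stay finite. Genes
with zero mutation rate in every category of a trait carry no information
for that trait; their evidence is equalized across that trait's states
(posterior falls back to the prior component) with a logged warning.
Output tables are sorted by PP3 descending with a lexicographic gene-id
tie-break for reproducible reports.

## Synthetic data

The generator draws each gene's label from (π0..π3), then per trait and
category draws γ ~ Gamma(γ̄β, β) for risk genes and the count from
Poisson(2Nμγ) (γ = 1 otherwise). Defaults are the study conditions used
throughout: 19,358 genes, π1^S = 0.05, π2^S = 0.03, two categories per
trait, 5,000/4,000 trios, mean relative risks 105/29 and 88/23, β = 1.
Mutation rates are synthesized as 10^z with z ~ Normal(−5, 0.6) truncated
to [−8, −3] — a stand-in matching the order of magnitude and spread of
exome-wide per-gene per-category rates (median 1e-5; per-category null
means 2Nμ mostly 0.01–1 at these trio counts). Real rate tables can be
passed as a drop-in array. What the generator does not emulate: the
empirical correlation of rates with gene length and GC content, shared
rate errors between traits, relatedness between cohorts, and annotation
misclassification — so passing calibration tests here demonstrates
correctness of the inference under the model, not robustness to real-data
rate misspecification.

A misdiagnosis option contaminates counts as if a fraction ρ of one
trait's trios are patients of the other trait, by redrawing counts with
mixed Poisson mean 2Nμ·((1−ρ)γ_eff1 + ρ·γ_eff2) (γ_eff = 1 for non-risk
genes). This is the count-level marginal of trio mis-assignment; it
reproduces the qualitative finding that imbalanced relative risks plus
ρ ≥ 5–10% inflate the estimated π3.

## Evaluation

Observed FDR (oFDR) at a threshold t is the fraction of genes called at
PP > t (strictly greater) whose latent label contradicts the call;
undefined (NaN) when nothing is called, never zero. AUC is computed by
the rank (Mann–Whitney) statistic with tie-averaging and is tested
exactly against an exhaustive pairwise oracle. The single-trait baseline
for power comparisons is the same machinery with the shared component
removed (the two-component posterior), not a separate codebase. The
false-positive shared proportion divides shared calls by all tested genes
in π3 = 0 simulations. Calibration points are cumulative (thresholded),
not binned.

The ancillary statistics are an upper-tail Poisson burden test
P(X ≥ y) at mean 2Nμ, and a permutation gene-set overlap test drawing
pairs of uniform subsets (partial Fisher–Yates, O(set size) per draw) and
applying (#{m > m₀}+1)/(N+1) with the strict inequality; a conventional
≥ variant is switchable. The permutation null is checked against the
hypergeometric law.

## Problem sizes and defaults in the replication harness

The calibration study uses 30 seeded replicates at full scale (19,358
genes) with the large-relative-risk configuration and π3 = 0.02; the
null-overlap study uses 4 configurations × 5 replicates with π3 = 0; π3
recovery uses 4 planted levels × 4 replicates; single-trait recovery uses
20 replicates at 19,358 genes. These sizes give stable means (doubling
replicates moves aggregate metrics well under the tolerances used) while
keeping the full harness in the minutes range on one CPU. At the
large-relative-risk settings the posteriors are sharply calibrated, so
mean oFDR at PP3 > 0.8 / > 0.5 sits well below the 0.1 / 0.25 anchors
associated with those thresholds in lower-power settings; the acceptance
checks treat the anchors as upper levels, consistent with calibration.

## Known limitations

Two traits only (the 2^N-hypothesis extension is out of scope); no
annotation-informed or per-gene priors; hyperparameters enter the joint
stage as plug-in point estimates, so π3 credible intervals do not
propagate single-trait estimation uncertainty; misdiagnosis is modeled at
the count level, not jointly estimated; case-control likelihoods and
transmitted variants are out of scope.
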