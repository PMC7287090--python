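# duotada

Two-trait empirical-Bayes joint analysis of de novo mutations (DNMs).

Parent-offspring trio studies of neurodevelopmental disorders, epileptic
encephalopathies, schizophrenia and congenital heart disease each report
gene-level DNM counts — and many risk genes are shared between disorders.
`duotada` jointly analyzes two such studies to (i) estimate the proportion
of risk genes the two traits share, (ii) turn that shared signal into more
powerful per-gene risk-gene discovery for each trait, and (iii) classify
every gene as risk for neither, one, or both traits. It is aimed at
statistical geneticists working with gene-level DNM summary tables
(per-gene mutation rates and counts, stratified by variant category such
as loss-of-function and damaging missense).

## Model

For gene *i* with mutation rate μᵢ in a study of *N* trios, the DNM count
in a category is

- non-risk gene: x ~ Poisson(2Nμᵢ)
- risk gene:  x ~ Poisson(2Nμᵢγ), γ ~ Gamma(γ̄β, β)

so the risk-gene marginal is negative binomial with shape r = γ̄β and
success probability β/(β + 2Nμᵢ). With two traits each gene falls under
one of four hypotheses — H₀ (neither), H₁ (trait 1 only), H₂ (trait 2
only), H₃ (both) — with prior weights

π₁ = π₁ˢ − π₃,  π₂ = π₂ˢ − π₃,  π₀ = 1 − (π₁ˢ + π₂ˢ − π₃),

where π₁ˢ, π₂ˢ are the single-trait risk-gene proportions (estimated
per trait by a two-component mixture fit, together with γ̄ and β) and π₃,
the shared proportion, is the one parameter estimated jointly — by a
dense-grid posterior over [0, min(π₁ˢ, π₂ˢ)] (default) or random-walk
Metropolis. Each gene then gets posterior probabilities PP₀..PP₃; PP₁+PP₃
and PP₂+PP₃ summarize the per-trait evidence, and the gene-level genetic
overlap is gO = 100% × π₃/(π₁+π₂+π₃).

## Worked example

`python examples/01_joint_analysis.py` simulates 19,358 genes for two
traits (5,000 and 4,000 trios, mean relative risks 105/29 and 88/23 over
two variant categories, 5%/3% risk genes of which 2% shared) and runs the
joint analysis:

```
pi3 mode     = 0.0204  (planted 0.02)
pi3 95% CI   = (0.0192, 0.0214)
genetic overlap gO = 34.1%  CI = (31.6%, 36.6%)

Top 5 genes by PP3 (posterior probability of being a shared risk gene):
gene_id   PP3  PP_trait1  PP_trait2
 g00071 1.000      1.000      1.000
 ...
Latent truth of those genes (3 = shared risk gene): [3, 3, 3, 3, 3]
```

The shared proportion is recovered within half a percent of genes, the
implied genetic overlap is ~34% (0.02 shared out of 0.06 total risk
proportion), and the top-ranked genes are exactly the planted shared risk
genes. The other examples fit single-trait hyperparameters
(`02_single_trait_fit.py`), check posterior calibration against latent
truth (`03_calibration_check.py`: mean observed FDR 0.004 at PP3 > 0.8),
and run the ancillary permutation-overlap and Poisson burden tests
(`04_overlap_and_burden_tests.py`).

A thin CLI mirrors the library (`duotada simulate | single | joint |
evaluate | poisson-test | overlap-test`); gene tables are TSV with
`gene_id`, `mut_rate_t{t}_c{c}`, `dn_t{t}_c{c}` columns.

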