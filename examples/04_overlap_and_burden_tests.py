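"""Ancillary tests: gene-set overlap by permutation, per-gene Poisson burden.

The permutation test asks whether two prioritized gene lists share more
members than random same-size sets would; the Poisson test asks whether
one gene carries more de novo mutations than its mutation rate predicts.
"""

import duotada as dt

# Two gene lists of sizes 33 and 25 from a 19,358-gene background share 8
# members — far beyond what chance produces (expected overlap ~0.04).
res = dt.permutation_overlap_test(
    background_size=19_358, size_a=33, size_b=25, observed_overlap=8,
    n_perm=10_000, seed=2, keep_null=True,
)
print(f"overlap permutation p = {res.p_value:.3g} "
      f"(max null overlap seen: {res.null_draws.max()})")

# A gene with 3 qualifying DNMs in 1,241 trios at mutation rate 2e-6:
p = dt.poisson_gene_test(3, 2e-6, 1241)
print(f"Poisson burden p for 3 DNMs at mu=2e-6, N=1241: {p:.3g}")
# Under the null the expected count is 2*N*mu ~ 0.005, so even a handful
# of DNMs in independent data is strong evidence of association.
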