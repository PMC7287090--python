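"""Observed FDR of shared-gene calls on simulated data.

Runs a few seeded replicates of the generative model, calls shared risk
genes at PP3 thresholds, and reports the observed false discovery rate
against the latent truth — the calibration check behind using posterior
probabilities directly for gene discovery.
"""

import numpy as np

import duotada as dt

configs = [dt.SimConfig(n_genes=19_358, pi3=0.02, label="large_mrr")]
df = dt.run_scenario_grid(configs, n_replicates=5, seed=123)

for t in (0.5, 0.8):
    print(f"mean oFDR at PP3 > {t}: {np.nanmean(df[f'ofdr_pp3_{t}']):.4f}")
print(f"mean estimated pi3: {df['pi3_hat'].mean():.4f} (planted 0.02)")
print(f"mean shared genes called at PP3 > 0.8: {df['genes_pp3_0.8'].mean():.0f}")
# A calibrated posterior keeps the oFDR at or below 1 - threshold;
# at these relative risks most calls are near-certain, so it sits well
# below the 0.2 / 0.5 ceilings.
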