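import numpy as np
import pytest

import duotada as dt


@pytest.fixture
def tiny_table() -> dt.GeneTable:
    """Three genes, two categories per trait, hand-sized numbers."""
    return dt.GeneTable(
        ["geneA", "geneB", "geneC"],
        mu1=[[1e-5, 2e-5], [5e-6, 1e-5], [2e-5, 3e-5]],
        x1=[[0, 1], [0, 0], [3, 2]],
        mu2=[[1e-5, 2e-5], [5e-6, 1e-5], [2e-5, 3e-5]],
        x2=[[1, 0], [0, 0], [2, 4]],
    )


@pytest.fixture
def params_pair() -> tuple[dt.TraitHyperParams, dt.TraitHyperParams]:
    p1 = dt.TraitHyperParams(n_trios=5000, mean_rr=(105.0, 29.0), dispersion=(1.0, 1.0), pi_single=0.05)
    p2 = dt.TraitHyperParams(n_trios=4000, mean_rr=(88.0, 23.0), dispersion=(1.0, 1.0), pi_single=0.03)
    return p1, p2


@pytest.fixture
def small_sim() -> tuple[dt.GeneTable, dt.SimTruth, dt.SimConfig]:
    """A 4,000-gene simulated dataset with a planted shared component."""
    cfg = dt.SimConfig(n_genes=4000, pi3=0.02)
    table, truth = dt.simulate_joint_dataset(cfg, seed=11)
    return table, truth, cfg
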