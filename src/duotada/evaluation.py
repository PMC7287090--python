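"""Calibration and classification metrics for simulated-truth experiments.

The key quantity is the observed false discovery rate (oFDR): among genes
called at a posterior-probability threshold, the fraction whose latent
label contradicts the call. A well-calibrated posterior gives
oFDR ~ E[1 - PP | called]. The joint model is compared against the
single-trait two-component baseline (the same machinery with the shared
component removed), via gene counts at a threshold and ROC AUCs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model_core import single_trait_posterior
from .types import CalibrationPoint, GeneTable, SimConfig, SimTruth

__all__ = [
    "observed_fdr",
    "roc_auc",
    "fp_shared_proportion",
    "gene_count_at_threshold",
    "pi3_recovery_summary",
    "evaluate_replicate",
]


def observed_fdr(scores, truth, threshold: float) -> CalibrationPoint:
    """oFDR at a posterior-probability cutoff (strict `score > threshold`).

    ``truth`` is boolean (or 0/1): whether each gene really belongs to the
    hypothesis being called. Undefined (NaN) when nothing is called.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError(f"scores and truth misaligned: {scores.shape} vs {truth.shape}")
    called = scores > threshold
    n_called = int(called.sum())
    n_false = int((called & ~truth).sum())
    return CalibrationPoint(threshold=threshold, n_called=n_called, n_false=n_false)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Tied scores are rank-averaged, equivalent to the trapezoidal area over
    the threshold sweep.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def fp_shared_proportion(
    pp3, truth_labels, thresholds: Sequence[float], n_genes: int | None = None
) -> dict[float, float]:
    """Per-threshold proportion of genes called shared when none truly are.

    Intended for datasets simulated with pi3 = 0, where every shared call
    is a false positive; the denominator is the total tested genes.
    """
    pp3 = np.asarray(pp3, dtype=float)
    labels = np.asarray(truth_labels)
    if np.any(labels == 3):
        raise ValueError("fp_shared_proportion expects truth generated with pi3 = 0")
    n = n_genes if n_genes is not None else pp3.size
    return {float(t): float(np.sum(pp3 > t)) / n for t in thresholds}


def gene_count_at_threshold(scores, threshold: float) -> int:
    """Number of genes with score strictly above the cutoff."""
    return int(np.sum(np.asarray(scores, dtype=float) > threshold))


def pi3_recovery_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Planted-vs-estimated pi3 agreement per scenario configuration.

    Expects columns ``config``, ``pi3_true``, ``pi3_hat`` with >= 3 distinct
    planted values per config; emits Pearson correlation and mean signed
    bias. A config with degenerate variance gets correlation NaN and a flag.
    """
    required = {"config", "pi3_true", "pi3_hat"}
    if not required.issubset(results.columns):
        raise ValueError(f"results table must contain columns {sorted(required)}")
    rows = []
    for name, grp in results.groupby("config"):
        planted = grp["pi3_true"].to_numpy(dtype=float)
        est = grp["pi3_hat"].to_numpy(dtype=float)
        if np.unique(planted).size < 3:
            raise ValueError(f"config {name!r}: need >= 3 distinct planted pi3 values")
        degenerate = np.std(planted) == 0 or np.std(est) == 0
        corr = float("nan") if degenerate else float(np.corrcoef(planted, est)[0, 1])
        rows.append(
            {
                "config": name,
                "correlation": corr,
                "mean_bias": float(np.mean(est - planted)),
                "n": len(grp),
                "degenerate_variance": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)


def evaluate_replicate(
    table: GeneTable,
    truth: SimTruth,
    result,
    config: SimConfig,
    thresholds: Sequence[float] = (0.5, 0.8, 0.95),
) -> dict:
    """Score one simulated replicate against its latent truth.

    Returns a flat dict: oFDR at each threshold for the shared and
    per-trait calls, AUCs of the joint model and the single-trait
    baseline, and gene counts at PP > 0.8.
    """
    pp = result.posteriors.set_index("gene_id").loc[table.gene_ids.astype(str)]
    pp3 = pp["PP3"].to_numpy()
    ppt1 = pp["PP_trait1"].to_numpy()
    ppt2 = pp["PP_trait2"].to_numpy()
    shared = truth.labels == 3
    risk1 = truth.risk_mask(1)
    risk2 = truth.risk_mask(2)

    base1 = single_trait_posterior(table.x1, table.mu1, config.trait1_params())
    base2 = single_trait_posterior(table.x2, table.mu2, config.trait2_params())

    out: dict = {}
    for t in thresholds:
        out[f"ofdr_pp3_{t}"] = observed_fdr(pp3, shared, t).ofdr
        out[f"ofdr_trait1_{t}"] = observed_fdr(ppt1, risk1, t).ofdr
        out[f"ofdr_trait2_{t}"] = observed_fdr(ppt2, risk2, t).ofdr
    if config.pi3 == 0:
        for t, v in fp_shared_proportion(pp3, truth.labels, thresholds).items():
            out[f"fp_shared_{t}"] = v
    for trait, scores, base, mask in (
        (1, ppt1, base1, risk1),
        (2, ppt2, base2, risk2),
    ):
        if mask.any() and not mask.all():
            out[f"auc_joint_trait{trait}"] = roc_auc(scores, mask)
            out[f"auc_single_trait{trait}"] = roc_auc(base, mask)
        out[f"genes_joint_trait{trait}"] = gene_count_at_threshold(scores, 0.8)
        out[f"genes_single_trait{trait}"] = gene_count_at_threshold(base, 0.8)
    out["genes_pp3_0.8"] = gene_count_at_threshold(pp3, 0.8)
    return out
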