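"""Readers and writers for gene tables, configs, fits, and estimates.

Gene tables are TSV with a ``gene_id`` column plus, for trait t and
category c, paired columns ``mut_rate_t{t}_c{c}`` and ``dn_t{t}_c{c}``.
Category arity is discovered from the header and may differ between
traits. Floats are serialized with 6 significant digits; full precision
is kept in memory.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import GeneTable, Pi3Estimate, SingleTraitFit, TraitHyperParams

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_config",
    "fit_to_json",
    "fit_from_json",
    "estimate_to_dict",
]

_COL_RE = re.compile(r"^(mut_rate|dn)_t([12])_c(\d+)$")


def _discover_categories(columns) -> dict[int, int]:
    """Number of categories per trait from header columns; validates pairing."""
    seen: dict[tuple[int, int], set[str]] = {}
    for col in columns:
        m = _COL_RE.match(col)
        if m:
            kind, trait, cat = m.group(1), int(m.group(2)), int(m.group(3))
            seen.setdefault((trait, cat), set()).add(kind)
    n_cat = {1: 0, 2: 0}
    for trait in (1, 2):
        cats = sorted(c for (t, c) in seen if t == trait)
        if not cats:
            raise ValueError(f"no trait-{trait} columns found in header")
        if cats != list(range(1, len(cats) + 1)):
            raise ValueError(f"trait-{trait} categories must be contiguous from 1, got {cats}")
        for c in cats:
            if seen[(trait, c)] != {"mut_rate", "dn"}:
                raise ValueError(f"trait {trait} category {c}: need both mut_rate and dn columns")
        n_cat[trait] = len(cats)
    return n_cat


def read_gene_table(path: str | Path) -> GeneTable:
    """Parse a gene-table TSV; errors cite the offending data line."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    n_cat = _discover_categories(df.columns)

    def parse(col: str, kind: str) -> np.ndarray:
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() | (vals < 0)
        if kind == "count":
            bad |= vals.notna() & (vals % 1 != 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: line {line}: column {col} has invalid value {raw[bad.idxmax()]!r} "
                f"(expected a non-negative {'integer' if kind == 'count' else 'real'})"
            )
        return vals.to_numpy(dtype=float)

    mu1 = np.column_stack([parse(f"mut_rate_t1_c{c}", "rate") for c in range(1, n_cat[1] + 1)])
    x1 = np.column_stack([parse(f"dn_t1_c{c}", "count") for c in range(1, n_cat[1] + 1)])
    mu2 = np.column_stack([parse(f"mut_rate_t2_c{c}", "rate") for c in range(1, n_cat[2] + 1)])
    x2 = np.column_stack([parse(f"dn_t2_c{c}", "count") for c in range(1, n_cat[2] + 1)])
    ids = df["gene_id"].to_numpy(dtype=object)
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    return GeneTable(ids, mu1, x1.astype(int), mu2, x2.astype(int))


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    cols: dict[str, object] = {"gene_id": table.gene_ids.astype(str)}
    for trait, mus, xs in ((1, table.mu1, table.x1), (2, table.mu2, table.x2)):
        for c in range(mus.shape[1]):
            cols[f"mut_rate_t{trait}_c{c + 1}"] = [f"{v:.6g}" for v in mus[:, c]]
            cols[f"dn_t{trait}_c{c + 1}"] = xs[:, c]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    """Load a YAML/JSON run config and validate the trait blocks."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("trait1", "trait2"):
        block = cfg.get(key)
        if block is not None:
            if "n_trios" not in block or int(block["n_trios"]) < 1:
                raise ValueError(f"{path}: {key}.n_trios must be a positive integer")
    return cfg


def hyperparams_from_config(block: dict) -> TraitHyperParams:
    return TraitHyperParams(
        n_trios=int(block["n_trios"]),
        mean_rr=tuple(float(g) for g in block["mean_rr"]),
        dispersion=tuple(float(b) for b in block["dispersion"]),
        pi_single=float(block["pi_single"]),
    )


def fit_to_json(fit: SingleTraitFit, path: str | Path) -> None:
    payload = {
        "pi_single": fit.pi_single,
        "mean_rr": list(fit.mean_rr),
        "dispersion": list(fit.dispersion),
        "n_trios": fit.n_trios,
        "log_likelihood": fit.log_likelihood,
        "method": fit.method,
        "flags": fit.flags,
    }
    if fit.diagnostics is not None:
        payload["diagnostics"] = {
            "rhat": fit.diagnostics.rhat,
            "n_chains": fit.diagnostics.n_chains,
            "n_steps": fit.diagnostics.n_steps,
            "n_kept": fit.diagnostics.n_kept,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def fit_from_json(path: str | Path) -> SingleTraitFit:
    payload = json.loads(Path(path).read_text())
    return SingleTraitFit(
        pi_single=float(payload["pi_single"]),
        mean_rr=tuple(payload["mean_rr"]),
        dispersion=tuple(payload["dispersion"]),
        n_trios=int(payload["n_trios"]),
        log_likelihood=float(payload["log_likelihood"]),
        method=payload.get("method", "map"),
        flags=list(payload.get("flags", [])),
    )


def estimate_to_dict(result, config=None) -> dict:
    """JSON-ready summary of a joint run: pi3, gO, diagnostics, config echo."""
    est: Pi3Estimate = result.pi3
    out = {
        "pi3_mode": est.mode,
        "pi3_ci": [est.ci_low, est.ci_high],
        "pi3_method": est.method,
        "gO_mode": result.genetic_overlap,
        "gO_ci": list(result.genetic_overlap_ci),
    }
    if result.diagnostics is not None:
        out["rhat"] = result.diagnostics.rhat
    if config is not None:
        out["config"] = {
            "method": config.method,
            "grid_size": config.grid_size,
            "n_chains": config.n_chains,
            "n_steps": config.n_steps,
            "n_kept": config.n_kept,
            "seed": config.seed,
            "prior": list(config.prior) if config.prior else None,
        }
    return out
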