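"""Domain containers for two-trait de novo mutation (DNM) analysis.

The unit of data is a gene: for each trait and each variant-annotation
category (e.g. loss-of-function, damaging missense) it carries a per-gene
mutation rate ``mu`` and an observed DNM count. Trait-level hyperparameters
(trio count N, per-category mean relative risk gamma-bar and Gamma
dispersion beta, single-trait risk-gene proportion pi_S) are estimated
once per trait and shared by every gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CategoryData",
    "GeneRecord",
    "GeneTable",
    "TraitHyperParams",
    "JointPriors",
    "GenePosterior",
    "SingleTraitFit",
    "SamplerDiagnostics",
    "Pi3Estimate",
    "SimConfig",
    "SimTruth",
    "CalibrationPoint",
    "OverlapTestResult",
]

_PRIOR_SUM_TOL = 1e-12


@dataclass(frozen=True)
class CategoryData:
    """One variant category of one gene for one trait: rate and count."""

    mu: float
    count: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or self.mu < 0:
            raise ValueError(f"mutation rate must be finite and >= 0, got {self.mu}")
        if int(self.count) != self.count or self.count < 0:
            raise ValueError(f"DNM count must be a non-negative integer, got {self.count}")


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene data for both traits, one CategoryData per variant category."""

    gene_id: str
    trait1: tuple[CategoryData, ...]
    trait2: tuple[CategoryData, ...]

    def __post_init__(self) -> None:
        if len(self.trait1) == 0 or len(self.trait2) == 0:
            raise ValueError(f"gene {self.gene_id}: each trait needs >= 1 category")


@dataclass(frozen=True)
class TraitHyperParams:
    """Trait-level hyperparameters of the Poisson-Gamma DNM model.

    ``mean_rr[c]`` is the prior mean relative risk (gamma-bar) of category
    ``c`` and ``dispersion[c]`` the Gamma rate-like parameter beta, so
    relative risks follow Gamma(gamma-bar * beta, beta). ``pi_single`` is
    the trait's marginal proportion of risk genes (pi^S).
    """

    n_trios: int
    mean_rr: tuple[float, ...]
    dispersion: tuple[float, ...]
    pi_single: float

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if len(self.mean_rr) != len(self.dispersion):
            raise ValueError("mean_rr and dispersion must have equal length")
        if len(self.mean_rr) == 0:
            raise ValueError("at least one category is required")
        for g, b in zip(self.mean_rr, self.dispersion):
            if not (np.isfinite(g) and g > 0 and np.isfinite(b) and b > 0):
                raise ValueError(f"mean_rr and dispersion must be finite and > 0, got {g}, {b}")
        if not 0.0 < self.pi_single < 1.0:
            raise ValueError(f"pi_single must lie strictly in (0,1), got {self.pi_single}")

    @property
    def n_categories(self) -> int:
        return len(self.mean_rr)


@dataclass(frozen=True)
class JointPriors:
    """Mixture weights over the four gene hypotheses.

    H0 neither trait, H1 trait 1 only, H2 trait 2 only, H3 both traits.
    """

    pi0: float
    pi1: float
    pi2: float
    pi3: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < 0):
            raise ValueError(f"mixture weights must be >= 0, got {vec}")
        if abs(vec.sum() - 1.0) > _PRIOR_SUM_TOL:
            raise ValueError(f"mixture weights must sum to 1, got sum {vec.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1, self.pi2, self.pi3], dtype=float)

    @property
    def pi1_single(self) -> float:
        """Marginal trait-1 risk proportion pi1^S = pi1 + pi3."""
        return self.pi1 + self.pi3

    @property
    def pi2_single(self) -> float:
        return self.pi2 + self.pi3


@dataclass(frozen=True)
class GenePosterior:
    """Posterior probabilities PP0..PP3 of one gene plus per-trait sums."""

    gene_id: str
    pp: np.ndarray

    def __post_init__(self) -> None:
        pp = np.asarray(self.pp, dtype=float)
        object.__setattr__(self, "pp", pp)
        if pp.shape != (4,):
            raise ValueError("pp must be a 4-vector")
        if abs(pp.sum() - 1.0) > 1e-10 or np.any(pp < -1e-15) or np.any(pp > 1 + 1e-15):
            raise ValueError(f"pp must be a probability 4-vector summing to 1, got {pp}")

    @property
    def pp_trait1(self) -> float:
        """Evidence that the gene is a trait-1 risk gene: PP1 + PP3."""
        return float(self.pp[1] + self.pp[3])

    @property
    def pp_trait2(self) -> float:
        return float(self.pp[2] + self.pp[3])


class GeneTable:
    """Column-oriented gene table: counts and rates as dense arrays.

    The array form is what every numerical routine consumes; ``records``
    gives the equivalent list of :class:`GeneRecord`. Category order is
    positional and must match the trait's hyperparameter order.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        mu1: np.ndarray,
        x1: np.ndarray,
        mu2: np.ndarray,
        x2: np.ndarray,
    ) -> None:
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        self.mu1 = np.atleast_2d(np.asarray(mu1, dtype=float))
        self.x1 = np.atleast_2d(np.asarray(x1, dtype=int))
        self.mu2 = np.atleast_2d(np.asarray(mu2, dtype=float))
        self.x2 = np.atleast_2d(np.asarray(x2, dtype=int))
        n = len(self.gene_ids)
        for name, arr in (("mu1", self.mu1), ("x1", self.x1), ("mu2", self.mu2), ("x2", self.x2)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows for {n} genes")
        if self.mu1.shape != self.x1.shape or self.mu2.shape != self.x2.shape:
            raise ValueError("rate and count arrays must have matching shapes per trait")
        if np.any(self.mu1 < 0) or np.any(self.mu2 < 0):
            raise ValueError("mutation rates must be >= 0")
        if np.any(self.x1 < 0) or np.any(self.x2 < 0):
            raise ValueError("DNM counts must be >= 0")
        ids, counts = np.unique(self.gene_ids.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate gene ids: {ids[counts > 1][:5].tolist()}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def n_categories(self) -> tuple[int, int]:
        return self.mu1.shape[1], self.mu2.shape[1]

    @property
    def records(self) -> list[GeneRecord]:
        out = []
        for i, gid in enumerate(self.gene_ids):
            t1 = tuple(CategoryData(float(m), int(c)) for m, c in zip(self.mu1[i], self.x1[i]))
            t2 = tuple(CategoryData(float(m), int(c)) for m, c in zip(self.mu2[i], self.x2[i]))
            out.append(GeneRecord(str(gid), t1, t2))
        return out

    @classmethod
    def from_records(cls, records: Sequence[GeneRecord]) -> "GeneTable":
        if not records:
            raise ValueError("empty record list")
        c1 = len(records[0].trait1)
        c2 = len(records[0].trait2)
        for r in records:
            if len(r.trait1) != c1 or len(r.trait2) != c2:
                raise ValueError(f"gene {r.gene_id}: inconsistent category arity")
        return cls(
            [r.gene_id for r in records],
            np.array([[c.mu for c in r.trait1] for r in records]),
            np.array([[c.count for c in r.trait1] for r in records]),
            np.array([[c.mu for c in r.trait2] for r in records]),
            np.array([[c.count for c in r.trait2] for r in records]),
        )

    def swap_traits(self) -> "GeneTable":
        """Relabel trait 1 as trait 2 and vice versa."""
        return GeneTable(self.gene_ids, self.mu2, self.x2, self.mu1, self.x1)


@dataclass
class SamplerDiagnostics:
    """Convergence summary of the Metropolis sampler (split-Rhat etc.)."""

    rhat: dict[str, float]
    n_chains: int
    n_steps: int
    n_kept: int
    flags: list[str] = field(default_factory=list)


@dataclass
class SingleTraitFit:
    """Estimated single-trait hyperparameters (the upstream sub-model).

    Produced by MAP optimization (default) or Metropolis sampling of the
    two-component mixture: a gene is a risk gene with probability
    ``pi_single`` and its counts then follow the Poisson-Gamma alternative.
    """

    pi_single: float
    mean_rr: tuple[float, ...]
    dispersion: tuple[float, ...]
    n_trios: int
    log_likelihood: float
    method: str = "map"
    diagnostics: SamplerDiagnostics | None = None
    flags: list[str] = field(default_factory=list)

    def to_hyperparams(self) -> TraitHyperParams:
        return TraitHyperParams(
            n_trios=self.n_trios,
            mean_rr=tuple(self.mean_rr),
            dispersion=tuple(self.dispersion),
            pi_single=self.pi_single,
        )


@dataclass
class Pi3Estimate:
    """Posterior summary of the shared risk-gene proportion pi3."""

    mode: float
    ci_low: float
    ci_high: float
    support: tuple[float, float]
    method: str = "grid"
    samples: np.ndarray | None = None
    grid: np.ndarray | None = None
    grid_density: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not (lo - 1e-12 <= self.ci_low <= self.mode + 1e-9 and self.mode - 1e-9 <= self.ci_high <= hi + 1e-12):
            raise ValueError(
                f"require ci_low <= mode <= ci_high within support, got "
                f"({self.ci_low}, {self.mode}, {self.ci_high}) on [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for a synthetic two-trait DNM dataset."""

    n_genes: int = 19_358
    pi1_single: float = 0.05
    pi2_single: float = 0.03
    pi3: float = 0.0
    n_trios1: int = 5_000
    n_trios2: int = 4_000
    mean_rr1: tuple[float, ...] = (105.0, 29.0)
    mean_rr2: tuple[float, ...] = (88.0, 23.0)
    dispersion1: tuple[float, ...] = (1.0, 1.0)
    dispersion2: tuple[float, ...] = (1.0, 1.0)
    misdiagnosis_rate: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.pi3 <= min(self.pi1_single, self.pi2_single) + 1e-12:
            raise ValueError("pi3 must lie in [0, min(pi1_single, pi2_single)]")
        if not 0 <= self.misdiagnosis_rate <= 0.5:
            raise ValueError("misdiagnosis_rate must lie in [0, 0.5]")
        if len(self.mean_rr1) != len(self.dispersion1) or len(self.mean_rr2) != len(self.dispersion2):
            raise ValueError("mean_rr and dispersion lengths must match per trait")

    def trait1_params(self) -> TraitHyperParams:
        return TraitHyperParams(self.n_trios1, self.mean_rr1, self.dispersion1, self.pi1_single)

    def trait2_params(self) -> TraitHyperParams:
        return TraitHyperParams(self.n_trios2, self.mean_rr2, self.dispersion2, self.pi2_single)


@dataclass
class SimTruth:
    """Latent state of a simulated dataset: model labels and gamma draws."""

    labels: np.ndarray  # (n_genes,) ints in {0,1,2,3}
    gamma1: np.ndarray  # (n_genes, C1) latent relative risks, 1 where not a risk gene
    gamma2: np.ndarray  # (n_genes, C2)

    def risk_mask(self, trait: int) -> np.ndarray:
        """Boolean mask of genes that are risk genes for the given trait (1 or 2)."""
        if trait == 1:
            return (self.labels == 1) | (self.labels == 3)
        if trait == 2:
            return (self.labels == 2) | (self.labels == 3)
        raise ValueError("trait must be 1 or 2")


@dataclass(frozen=True)
class CalibrationPoint:
    """Observed FDR at one posterior-probability threshold."""

    threshold: float
    n_called: int
    n_false: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_false <= self.n_called:
            raise ValueError("require 0 <= n_false <= n_called")

    @property
    def ofdr(self) -> float:
        """False calls over total calls; NaN (undefined) when nothing is called."""
        if self.n_called == 0:
            return float("nan")
        return self.n_false / self.n_called


@dataclass
class OverlapTestResult:
    """Permutation test of the overlap between two gene sets."""

    observed: int
    n_perm: int
    p_value: float
    null_draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        floor = 1.0 / (self.n_perm + 1)
        if not floor - 1e-15 <= self.p_value <= 1.0 + 1e-15:
            raise ValueError(f"p-value must lie in [1/(N+1), 1], got {self.p_value}")
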