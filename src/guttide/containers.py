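"""Core in-memory containers shared across the pipeline.

The universal currency is the :class:`AsvTable`: an integer count matrix with
samples as rows and ASVs (amplicon sequence variants) as columns.  Everything
downstream — diversity, null models, SparCC, association — consumes either the
raw counts or per-sample relative abundances derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

SITES = ("Oc", "R", "F")
TIMEPOINTS = ("1W", "2W", "1M", "2M")

VFA_COMPONENTS = ("ACE", "PRO", "IBUT", "BUT", "IVAL", "VAL")
COVARIATE_NAMES = VFA_COMPONENTS + (
    "TVFA",
    "ACE.PRO.ratio",
    "Glu",
    "TG",
    "TP",
    "Tbil",
    "Ca",
    "P",
    "Fe",
    "Mg",
)

TAXONOMIC_RANKS = ("phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Raised when an input artifact violates a structural invariant."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = list(labels)
    seen: set[str] = set()
    dups = [x for x in labels if x in seen or seen.add(x)]  # type: ignore[func-returns-value]
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(map(str, dups)))[:5]}")


class AsvTable:
    """Validated sample × ASV count matrix.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and ASV ids as columns.  Values
        must be non-negative integers and every sample must have a positive
        total count.
    """

    def __init__(self, counts: pd.DataFrame):
        _check_unique(counts.index, "sample ids")
        _check_unique(counts.columns, "ASV ids")
        values = counts.to_numpy()
        if values.size == 0:
            raise ValidationError("empty count table")
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(values.astype(float))):
            raise ValidationError("counts contain non-finite values")
        if np.any(values < 0):
            bad = counts.index[np.any(values < 0, axis=1)][0]
            raise ValidationError(f"negative count in sample {bad!r}")
        if np.any(values != np.floor(values)):
            bad = counts.index[np.any(values != np.floor(values), axis=1)][0]
            raise ValidationError(f"non-integer count in sample {bad!r}")
        totals = values.sum(axis=1)
        if np.any(totals == 0):
            bad = counts.index[totals == 0][0]
            raise ValidationError(f"sample {bad!r} has total count 0")
        self.counts = counts.astype(np.int64)

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample total counts (library sizes)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized counts; every row sums to 1."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def occupancy(self) -> pd.Series:
        """Fraction of samples in which each ASV is present."""
        return (self.counts > 0).mean(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        """Restrict to the given samples, dropping ASVs absent from all of them."""
        sub = self.counts.loc[list(sample_ids)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        return AsvTable(sub)

    def subset_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[:, list(asv_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"AsvTable({self.n_samples} samples x {self.n_asvs} ASVs)"


@dataclass
class GroupTestResult:
    """Outcome of a permutation or rank test for group differences."""

    method: str
    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int | None = None
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray  # descending, negatives clamped to zero
    proportion_explained: np.ndarray


@dataclass
class AssemblyResult:
    """Pairwise null-model statistics and the ecological-process fractions.

    Fractions follow the standard two-step null-model classification: selection is
    read off the phylogenetic-turnover z-score (βNTI), and the remaining
    pairs are split by the Raup–Crick Bray–Curtis statistic into dispersal
    limitation, homogenizing dispersal and drift.
    """

    beta_nti: pd.DataFrame
    rc_bray: pd.DataFrame
    fractions: dict[str, float]
    counts: dict[str, int]
    n_pairs: int
    n_flagged: int = 0
    n_null: int | None = None
    seed: int | None = None

    @property
    def selection_fraction(self) -> float:
        """Variable + homogeneous selection combined."""
        return self.fractions["variable_selection"] + self.fractions["homogeneous_selection"]


@dataclass
class SparccResult:
    """Basis correlations inferred from compositional counts."""

    rho: pd.DataFrame  # symmetric, unit diagonal, clipped to [-1, 1]
    t_var: pd.DataFrame  # log-ratio variances, symmetric, zero diagonal
    omega: pd.Series  # basis variances
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)  # taxa whose basis variance was clamped
    n_inner_iter: int = 20
    seed: int | None = None


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    regimes: dict[str, str]  # site -> assembly regime
    planted_rho: dict[tuple[str, str], float]
    covariate_loadings: pd.DataFrame  # covariate × (site_gradient, time_gradient)
    traits: pd.Series  # ASV -> Brownian trait value
    environment: pd.Series  # sample -> environmental optimum
    basis: pd.DataFrame  # sample × ASV latent relative abundances


@dataclass
class SyntheticDataset:
    """Bundle of all study artifacts plus the generating truth."""

    table: AsvTable
    tree: "object"  # skbio TreeNode
    metadata: pd.DataFrame
    covariates: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: SyntheticTruth
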