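"""Alpha diversity, compositional transforms, ordination and group tests.

Shannon entropy is reported in nats so that Pielou evenness J = H / ln(S)
is exact.  Between-sample structure uses the Aitchison geometry: a uniform
pseudocount, centered log-ratio (CLR) transform, Euclidean distance, and
classical PCoA.  Group differences are tested by PERMANOVA and ANOSIM
(seeded permutation tests) and alpha diversity by the Wilcoxon rank-sum
test (exact for small samples without ties, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova

from .containers import AsvTable, GroupTestResult, OrdinationResult

__all__ = [
    "shannon",
    "observed_asvs",
    "pielou",
    "alpha_diversity",
    "clr_transform",
    "aitchison_distance",
    "pcoa",
    "permanova",
    "anosim",
    "wilcoxon_rank_sum",
]


# ----------------------------------------------------------------- alpha
def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i in nats, over non-zero taxa."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_asvs(counts: np.ndarray) -> int:
    """Observed richness: number of taxa with count > 0."""
    return int((np.asarray(counts) > 0).sum())


def pielou(counts: np.ndarray) -> float:
    """Pielou evenness J = H / ln(S_obs); NaN when S_obs < 2 (undefined)."""
    s = observed_asvs(counts)
    if s < 2:
        return float("nan")
    return shannon(counts) / np.log(s)


def alpha_diversity(table: AsvTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), observed ASVs and Pielou evenness."""
    rows = {
        sid: {
            "shannon": shannon(row),
            "observed_asvs": observed_asvs(row),
            "pielou": pielou(row),
        }
        for sid, row in zip(table.sample_ids, table.counts.to_numpy())
    }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------- compositional
def clr_transform(table: AsvTable | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of each sample: ln(x_i / g(x)).

    A uniform ``pseudocount`` is added to every count first (zero
    replacement); each output row sums to 0.
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = counts.to_numpy(dtype=float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("zero entries remain; use a positive pseudocount")
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def aitchison_distance(table: AsvTable | pd.DataFrame, pseudocount: float = 1.0) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples."""
    clr = clr_transform(table, pseudocount)
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(clr.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=list(clr.index))


# -------------------------------------------------------------------- pcoa
def pcoa(dist: DistanceMatrix | pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Classical principal-coordinate analysis (Gower eigendecomposition).

    Negative eigenvalues (numerical noise when the input is Euclidean, as
    the Aitchison distance is) are clamped to zero and excluded from the
    proportion-explained denominator.
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.data
        ids = list(dist.ids)
    else:
        d = np.asarray(dist, dtype=float)
        ids = list(dist.index)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvals_clamped = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(eigvals_clamped)
    total = eigvals_clamped.sum()
    prop = eigvals_clamped / total if total > 0 else np.zeros(n)
    k = n_axes if n_axes is not None else int((eigvals_clamped > 1e-12 * max(total, 1.0)).sum())
    k = max(k, 1)
    coord_df = pd.DataFrame(
        coords[:, :k], index=ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=coord_df,
        eigenvalues=eigvals_clamped[:k],
        proportion_explained=prop[:k],
    )


# ----------------------------------------------------------- group tests
def _as_distance_matrix(dist: DistanceMatrix | pd.DataFrame) -> DistanceMatrix:
    if isinstance(dist, DistanceMatrix):
        return dist
    return DistanceMatrix(np.asarray(dist, dtype=float), ids=list(dist.index))


def _check_groups(groups: pd.Series) -> None:
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group {small.index[0]!r} has fewer than 2 samples")


def permanova(
    dist: DistanceMatrix | pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """One-way PERMANOVA: pseudo-F from the distance-based SS partition,
    permutation p = (hits + 1) / (n_perm + 1)."""
    dm = _as_distance_matrix(dist)
    grouping = groups.loc[list(dm.ids)]
    _check_groups(grouping)
    res = _skbio_permanova(dm, grouping.to_numpy(), permutations=n_perm, seed=seed)
    return GroupTestResult(
        method="PERMANOVA",
        statistic_name="pseudo-F",
        statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_perm,
        seed=seed,
    )


def anosim(
    dist: DistanceMatrix | pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (M/2)."""
    dm = _as_distance_matrix(dist)
    grouping = groups.loc[list(dm.ids)]
    _check_groups(grouping)
    res = _skbio_anosim(dm, grouping.to_numpy(), permutations=n_perm, seed=seed)
    return GroupTestResult(
        method="ANOSIM",
        statistic_name="R",
        statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_perm,
        seed=seed,
    )


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution when the combined sample size is <= 20 and there
    are no ties; otherwise the normal approximation with tie correction.
    The reported statistic is the rank sum W of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return GroupTestResult(
        method=f"Wilcoxon rank-sum ({method})",
        statistic_name="W",
        statistic=w,
        p_value=float(res.pvalue),
    )
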