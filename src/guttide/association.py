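"""Taxon–covariate association and envfit-style vector fitting.

Spearman rank correlations between (filtered) taxon abundances and
covariates, Benjamini–Hochberg adjusted; and a permutation test of how
strongly each covariate aligns with the ordination (squared multiple
correlation R² of the covariate on the retained PCoA axes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AsvTable, OrdinationResult

__all__ = [
    "filter_taxa",
    "spearman_matrix",
    "bh_adjust",
    "association_table",
    "envfit",
    "EnvfitResult",
    "aggregate_taxa",
]


def filter_taxa(
    table: AsvTable,
    min_mean_rel_abund: float = 1e-4,
    min_frequency: float = 0.5,
) -> AsvTable:
    """Keep taxa with mean relative abundance >= ``min_mean_rel_abund``
    (default 0.01%) AND occupancy >= ``min_frequency`` (boundary inclusive)."""
    if not (0 <= min_mean_rel_abund <= 1 and 0 <= min_frequency <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    mean_rel = table.relative_abundance().mean(axis=0)
    occ = table.occupancy()
    keep = mean_rel.index[(mean_rel >= min_mean_rel_abund) & (occ >= min_frequency)]
    if len(keep) == 0:
        raise ValueError("all taxa removed by the abundance/frequency filter")
    return table.subset_asvs(keep)


def aggregate_taxa(table: AsvTable, taxonomy: pd.DataFrame, rank: str = "genus") -> AsvTable:
    """Sum ASV counts within each taxon at the given rank."""
    if rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy")
    labels = taxonomy.loc[table.asv_ids, rank].fillna("unclassified")
    grouped = table.counts.T.groupby(labels.values).sum().T
    return AsvTable(grouped)


# ---------------------------------------------------------------- spearman
@lru_cache(maxsize=8)
def _exact_d2_distribution(n: int) -> np.ndarray:
    """Null distribution of sum of squared rank differences for sample size n."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=np.int64)
    return ((perms - base) ** 2).sum(axis=1)


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p_t = stats.spearmanr(x, y)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 10 and not ties:
        # exact permutation null on sum of squared rank differences
        d2 = ((stats.rankdata(x) - stats.rankdata(y)) ** 2).sum()
        null = _exact_d2_distribution(n)
        mid = n * (n * n - 1) / 6.0  # d2 value at rho = 0
        p = float(np.mean(np.abs(null - mid) >= abs(d2 - mid) - 1e-9))
        return float(rho), p
    return float(rho), float(p_t)


def spearman_matrix(
    taxa_abundances: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every (taxon, covariate) pair.

    Rows must be the same samples in both frames.  Ties get average ranks;
    p-values use exact enumeration for n <= 10 without ties, else the
    t-approximation.  Constant vectors yield NaN.
    """
    common = [s for s in taxa_abundances.index if s in set(covariates.index)]
    if len(common) < 4:
        raise ValueError("need at least 4 complete sample pairs")
    ta = taxa_abundances.loc[common]
    cv = covariates.loc[common]
    rho = pd.DataFrame(index=ta.columns, columns=cv.columns, dtype=float)
    pval = pd.DataFrame(index=ta.columns, columns=cv.columns, dtype=float)
    for taxon in ta.columns:
        xt = ta[taxon].to_numpy(dtype=float)
        for cov in cv.columns:
            r, p = _spearman_pair(xt, cv[cov].to_numpy(dtype=float))
            rho.loc[taxon, cov] = r
            pval.loc[taxon, cov] = p
    return rho, pval


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjustment, q_(i) = min_{j>=i} p_(j) m / j.

    NaNs are passed through untouched.
    """
    arr = np.asarray(p_values, dtype=float)
    flat = arr.ravel()
    mask = np.isfinite(flat)
    if np.any((flat[mask] < 0) | (flat[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(flat, np.nan)
    if mask.sum():
        out[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    out = out.reshape(arr.shape)
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index)
    return out


@dataclass
class AssociationTable:
    """Spearman associations with BH-adjusted q-values."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    family: str = "per_covariate"


def association_table(
    table: AsvTable,
    covariates: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    level: str = "asv",
    min_mean_rel_abund: float = 1e-4,
    min_frequency: float = 0.5,
    family: str = "per_covariate",
) -> AssociationTable:
    """Filtered taxon–covariate Spearman matrix with BH adjustment.

    ``family`` controls the BH family: ``"per_covariate"`` adjusts each
    covariate column across taxa (the heatmap-star convention),
    ``"global"`` adjusts all cells jointly.
    """
    if family not in ("per_covariate", "global"):
        raise ValueError("family must be 'per_covariate' or 'global'")
    if level == "genus":
        if taxonomy is None:
            raise ValueError("taxonomy required for genus-level association")
        table = aggregate_taxa(table, taxonomy, "genus")
    elif level != "asv":
        raise ValueError("level must be 'asv' or 'genus'")
    filtered = filter_taxa(table, min_mean_rel_abund, min_frequency)
    rel = filtered.relative_abundance()
    rho, p = spearman_matrix(rel, covariates)
    if family == "global":
        q = pd.DataFrame(
            np.asarray(bh_adjust(p.to_numpy())), index=p.index, columns=p.columns
        )
    else:
        q = p.apply(lambda col: bh_adjust(col), axis=0)
    return AssociationTable(rho=rho, p=p, q=q, family=family)


# ------------------------------------------------------------------ envfit
@dataclass
class EnvfitResult:
    """Vector fit of covariates onto ordination axes."""

    directions: pd.DataFrame  # covariate × axes, unit norm
    r2: pd.Series
    p: pd.Series
    n_permutations: int
    seed: int | None = None


def envfit(
    ordination: OrdinationResult | pd.DataFrame,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
    n_axes: int = 2,
) -> EnvfitResult:
    """Least-squares fit of each covariate onto the first ``n_axes``
    ordination axes, with a permutation test of R².

    R² is the squared multiple correlation of the (centered) covariate with
    the axis scores; the null permutes the covariate across samples,
    p = (hits + 1) / (n_perm + 1).  Constant covariates are rejected.
    """
    coords = (
        ordination.coordinates if isinstance(ordination, OrdinationResult) else ordination
    )
    if coords.shape[1] < n_axes:
        raise ValueError(f"ordination has fewer than {n_axes} axes")
    common = [s for s in coords.index if s in set(covariates.index)]
    x = coords.loc[common].to_numpy(dtype=float)[:, :n_axes]
    x = x - x.mean(axis=0)
    n = len(common)
    rng = np.random.default_rng(seed)
    # one shared set of permutations keeps covariates comparable
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    pinv = np.linalg.pinv(x)

    def fit_r2(y: np.ndarray) -> tuple[np.ndarray, float]:
        yc = y - y.mean()
        sst = float(yc @ yc)
        beta = pinv @ yc
        fitted = x @ beta
        r2 = float(fitted @ fitted) / sst
        return beta, r2

    directions = {}
    r2s = {}
    ps = {}
    for cov in covariates.columns:
        y = covariates.loc[common, cov].to_numpy(dtype=float)
        if np.all(y == y[0]):
            raise ValueError(f"covariate {cov!r} is constant")
        beta, r2 = fit_r2(y)
        hits = 0
        for k in range(n_perm):
            _, r2p = fit_r2(y[perms[k]])
            if r2p >= r2:
                hits += 1
        norm = np.linalg.norm(beta)
        directions[cov] = beta / norm if norm > 0 else beta
        r2s[cov] = r2
        ps[cov] = (hits + 1) / (n_perm + 1)
    return EnvfitResult(
        directions=pd.DataFrame(
            directions, index=[f"PC{i + 1}" for i in range(n_axes)]
        ).T,
        r2=pd.Series(r2s, name="r2"),
        p=pd.Series(ps, name="p"),
        n_permutations=n_perm,
        seed=seed if isinstance(seed, int) else None,
    )
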