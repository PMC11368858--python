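"""Null-model decomposition of community assembly processes.

Implements the two-step phylogenetic/taxonomic null-model framework for
quantifying which ecological processes drive community turnover:

1. βMNTD — the (abundance-weighted) mean distance from each taxon in one
   community to its nearest relative in the other — is standardized against
   a null that shuffles taxon identities across the phylogeny, giving the
   z-score βNTI.  |βNTI| > 2 indicates selection: variable selection when
   turnover exceeds the null (βNTI > +2), homogeneous selection when it
   falls below (βNTI < −2).
2. Pairs not attributed to selection are classified with the Raup–Crick
   metric on Bray–Curtis (RCbray): null communities preserve each sample's
   observed richness and total abundance, draw taxon identities in
   proportion to occupancy, and allocate abundance in proportion to
   metacommunity relative abundance.  RCbray > +0.95 → dispersal
   limitation, RCbray < −0.95 → homogenizing dispersal, |RCbray| ≤ 0.95 →
   drift.

The five resulting fractions over all sample pairs sum to 1.  Following the
study design, pairs are typically computed within each digestive-tract site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .containers import AssemblyResult, AsvTable
from .io import patristic_matrix

__all__ = [
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "raup_crick_bray",
    "assembly_fractions",
    "assembly_by_group",
    "PROCESSES",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


# ------------------------------------------------------------------ bMNTD
def beta_mntd(
    abund_i: np.ndarray,
    abund_j: np.ndarray,
    dmat: np.ndarray,
    weighted: bool = True,
) -> float:
    """βMNTD between two communities given a patristic distance matrix.

    ``beta_mntd = 0.5 * (sum_k f_ik * min_{m in j} d(k, m)
                       + sum_m f_jm * min_{k in i} d(m, k))``

    with ``f`` the relative abundances (``weighted=True``) or uniform
    weights over present taxa (``weighted=False``).  Taxa shared by both
    communities contribute a nearest-taxon distance of 0.
    """
    xi = np.asarray(abund_i, dtype=float)
    xj = np.asarray(abund_j, dtype=float)
    if xi.sum() == 0 or xj.sum() == 0:
        raise ValueError("both communities must be non-empty")
    pres_i = np.flatnonzero(xi > 0)
    pres_j = np.flatnonzero(xj > 0)
    if not weighted:
        xi = (xi > 0).astype(float)
        xj = (xj > 0).astype(float)
    fi = xi[pres_i] / xi.sum()
    fj = xj[pres_j] / xj.sum()
    d_ij = dmat[np.ix_(pres_i, pres_j)]
    return float(0.5 * ((fi * d_ij.min(axis=1)).sum() + (fj * d_ij.min(axis=0)).sum()))


def _nearest_taxon_matrix(presence: np.ndarray, dmat: np.ndarray) -> np.ndarray:
    """Row s, column k: distance from taxon k to its nearest taxon present
    in sample s (0 if k itself is present)."""
    n_samples, _ = presence.shape
    out = np.empty((n_samples, dmat.shape[0]))
    for s in range(n_samples):
        idx = np.flatnonzero(presence[s])
        out[s] = dmat[:, idx].min(axis=1)
    return out


def beta_mntd_matrix(
    table: AsvTable,
    tree: TreeNode | pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """Pairwise βMNTD over all samples (vectorized nearest-taxon form)."""
    dmat_df = tree if isinstance(tree, pd.DataFrame) else patristic_matrix(tree, table.asv_ids)
    dmat = dmat_df.loc[table.asv_ids, table.asv_ids].to_numpy()
    f = table.relative_abundance().to_numpy()
    if not weighted:
        pres = (f > 0).astype(float)
        f = pres / pres.sum(axis=1, keepdims=True)
    nearest = _nearest_taxon_matrix(f > 0, dmat)
    cross = f @ nearest.T  # [i, j] = sum_k f_ik * min_{m in j} d(k, m)
    bm = 0.5 * (cross + cross.T)
    np.fill_diagonal(bm, 0.0)
    return pd.DataFrame(bm, index=table.sample_ids, columns=table.sample_ids)


# ------------------------------------------------------------------- bNTI
def beta_nti(
    table: AsvTable,
    tree: TreeNode | pd.DataFrame,
    n_null: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
    weighted: bool = True,
    return_null_moments: bool = False,
):
    """βNTI: z-score of observed βMNTD against a taxon-shuffle null.

    The null shuffles taxon identities across the tips of the whole tree
    (equivalently, permutes rows/columns of the patristic matrix) and
    recomputes βMNTD for every sample pair, ``n_null`` times.  Pairs whose
    null standard deviation is 0 are flagged (NaN).

    Returns the βNTI DataFrame, or ``(bnti, null_mean, null_sd)`` when
    ``return_null_moments`` is set.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    dmat_df = tree if isinstance(tree, pd.DataFrame) else patristic_matrix(tree, table.asv_ids)
    dmat = dmat_df.loc[table.asv_ids, table.asv_ids].to_numpy()
    f = table.relative_abundance().to_numpy()
    if not weighted:
        pres = (f > 0).astype(float)
        f = pres / pres.sum(axis=1, keepdims=True)
    presence = f > 0

    def pair_matrix(d: np.ndarray) -> np.ndarray:
        nearest = _nearest_taxon_matrix(presence, d)
        cross = f @ nearest.T
        return 0.5 * (cross + cross.T)

    obs = pair_matrix(dmat)
    rng = np.random.default_rng(seed)
    n = table.n_samples
    mean_acc = np.zeros((n, n))
    m2_acc = np.zeros((n, n))
    for it in range(n_null):
        perm = rng.permutation(dmat.shape[0])
        null = pair_matrix(dmat[np.ix_(perm, perm)])
        delta = null - mean_acc
        mean_acc += delta / (it + 1)
        m2_acc += delta * (null - mean_acc)
    null_sd = np.sqrt(m2_acc / max(n_null - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean_acc) / null_sd
    z[null_sd == 0] = np.nan
    np.fill_diagonal(z, 0.0)
    ids = table.sample_ids
    bnti = pd.DataFrame(z, index=ids, columns=ids)
    if return_null_moments:
        return (
            bnti,
            pd.DataFrame(mean_acc, index=ids, columns=ids),
            pd.DataFrame(null_sd, index=ids, columns=ids),
        )
    return bnti


# ------------------------------------------------------------------ RCbray
def raup_crick_bray(
    table: AsvTable,
    n_null: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Raup–Crick metric on Bray–Curtis dissimilarity, rescaled to [-1, 1].

    For each null iteration every sample is rebuilt stochastically: its
    observed richness is kept, taxon identities are drawn without
    replacement with probability proportional to occupancy (Gumbel top-k
    weighted sampling), one individual seeds each drawn taxon and the
    remaining abundance is allocated multinomially in proportion to the
    metacommunity relative abundance.  Bray–Curtis between null samples is
    then compared with the observed value:

    ``RC = 2 * (P(B_null < B_obs) + 0.5 * P(B_null = B_obs)) - 1``
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = table.counts.to_numpy()
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("empty sample in table")
    n, s = counts.shape
    occupancy = (counts > 0).sum(axis=0).astype(float)
    meta = counts.sum(axis=0).astype(float)
    meta_p = meta / meta.sum()
    occ_p = occupancy / occupancy.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)

    obs_b = squareform(pdist(counts, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    less = np.zeros((n, n))
    equal = np.zeros((n, n))
    log_occ = np.log(occ_p, out=np.full(s, -np.inf), where=occ_p > 0)
    null_counts = np.empty((n, s), dtype=np.int64)
    for _ in range(n_null):
        gumbel = rng.gumbel(size=(n, s))
        keys = log_occ + gumbel
        null_counts[:] = 0
        for i in range(n):
            r = richness[i]
            chosen = np.argpartition(-keys[i], r - 1)[:r]
            null_counts[i, chosen] = 1
            remaining = totals[i] - r
            if remaining > 0:
                p = meta_p[chosen]
                psum = p.sum()
                if psum <= 0:
                    p = np.full(r, 1.0 / r)
                else:
                    p = p / psum
                null_counts[i, chosen] += rng.multinomial(remaining, p)
        null_b = squareform(pdist(null_counts, metric="braycurtis"))
        less += null_b < obs_b
        equal += np.isclose(null_b, obs_b, rtol=1e-12, atol=1e-12)
    rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


# --------------------------------------------------------------- fractions
def assembly_fractions(
    bnti: pd.DataFrame,
    rcbray: pd.DataFrame,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
    n_null: int | None = None,
    seed: int | None = None,
) -> AssemblyResult:
    """Classify every unordered sample pair into one of five processes.

    Selection first: βNTI > +t → variable selection, βNTI < −t →
    homogeneous selection.  Otherwise (|βNTI| ≤ t, including the boundary)
    the pair is classified by RCbray.  Pairs with an undefined βNTI
    (degenerate null) are excluded from the fractions and counted as
    flagged.
    """
    if list(bnti.index) != list(rcbray.index) or list(bnti.columns) != list(rcbray.columns):
        raise ValueError("βNTI and RCbray matrices must share sample labels")
    n = len(bnti)
    iu = np.triu_indices(n, k=1)
    b = bnti.to_numpy()[iu]
    r = rcbray.to_numpy()[iu]
    valid = np.isfinite(b) & np.isfinite(r)
    n_flagged = int((~valid).sum())
    b, r = b[valid], r[valid]
    counts = {
        "variable_selection": int((b > bnti_threshold).sum()),
        "homogeneous_selection": int((b < -bnti_threshold).sum()),
    }
    rest = np.abs(b) <= bnti_threshold
    counts["dispersal_limitation"] = int((rest & (r > rc_threshold)).sum())
    counts["homogenizing_dispersal"] = int((rest & (r < -rc_threshold)).sum())
    counts["drift"] = int((rest & (np.abs(r) <= rc_threshold)).sum())
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no valid sample pairs to classify")
    fractions = {k: v / total for k, v in counts.items()}
    return AssemblyResult(
        beta_nti=bnti,
        rc_bray=rcbray,
        fractions=fractions,
        counts=counts,
        n_pairs=total,
        n_flagged=n_flagged,
        n_null=n_null,
        seed=seed,
    )


def assembly_by_group(
    table: AsvTable,
    tree: TreeNode | pd.DataFrame,
    metadata: pd.DataFrame,
    by: str = "site",
    n_null: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
    weighted: bool = True,
) -> dict[str, AssemblyResult]:
    """Run the full decomposition separately within each level of ``by``
    (sites by default, matching the per-site reporting of the study)."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    results: dict[str, AssemblyResult] = {}
    levels = list(dict.fromkeys(metadata[by]))
    seeds = ss.spawn(2 * len(levels))
    for k, level in enumerate(levels):
        samples = metadata.index[metadata[by] == level]
        sub = table.subset_samples([s for s in table.sample_ids if s in set(samples)])
        bnti = beta_nti(sub, tree, n_null=n_null, seed=seeds[2 * k], weighted=weighted)
        rc = raup_crick_bray(sub, n_null=n_null, seed=seeds[2 * k + 1])
        results[level] = assembly_fractions(
            bnti, rc, bnti_threshold=bnti_threshold, rc_threshold=rc_threshold, n_null=n_null
        )
    return results
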