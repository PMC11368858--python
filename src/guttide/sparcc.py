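"""SparCC: basis correlations from compositional count data.

Sequencing counts are compositional — only relative abundances are observed
— so sample Pearson correlations between taxa are biased.  SparCC works in
log-ratio space: for every pair of taxa the variance of the log ratio

    t_ij = var(ln(x_i / x_j)) = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j)

depends on the unobservable basis variances omega and basis correlations
rho.  Assuming the correlation network is sparse (sum_j rho_ij ≈ 0), the
row sums t_i = sum_j t_ij reduce to a linear system

    t = M omega,   M = ones((D, D)) + (D - 2) * I

whose solution yields omega and hence rho.  Strongly correlated pairs
violate the sparsity assumption, so the strongest pair above a threshold is
iteratively removed from the system and omega re-solved.

Fractions are estimated Bayesianly: each inner iteration draws per-sample
taxon fractions from Dirichlet(counts + pseudocount) and the per-iteration
correlation estimates are averaged.

Pseudo-p-values come from a permutation null (each taxon's counts permuted
independently across samples, destroying all inter-taxon association while
preserving marginals) or, optionally, a sample-resampling bootstrap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AsvTable, SparccResult

__all__ = ["sparcc_correlation", "bootstrap_pvalues"]

_OMEGA_FLOOR = 1e-12


def _counts_frame(table: AsvTable | pd.DataFrame) -> pd.DataFrame:
    return table.counts if isinstance(table, AsvTable) else table


def _basis_solution(
    t: np.ndarray,
    n_exclusion_iter: int,
    exclusion_threshold: float,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]], np.ndarray]:
    """Solve for basis variances/correlations with iterative pair exclusion.

    The linear system generalizes to an arbitrary pattern of active pairs:
    ``t_i = deg_i * omega_i + sum_{j active with i} omega_j``.  After each
    solve the strongest remaining correlation above the threshold is
    excluded; a taxon excluded from nearly all of its pairs (fewer than 3
    active partners left) is dropped from the system entirely — its basis
    variance is then unidentifiable and it is reported as clamped/flagged.

    Returns (rho, omega, excluded_pairs, flagged_mask).
    """
    d = t.shape[0]
    active_pair = ~np.eye(d, dtype=bool)
    active_taxon = np.ones(d, dtype=bool)
    excluded: list[tuple[int, int]] = []
    flagged = np.zeros(d, dtype=bool)

    def solve() -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero(active_taxon)
        sub = active_pair[np.ix_(idx, idx)]
        m = sub.astype(float)
        np.fill_diagonal(m, sub.sum(axis=1))
        t_row = (t[np.ix_(idx, idx)] * sub).sum(axis=1)
        try:
            omega_sub = np.linalg.solve(m, t_row)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular basis system after excluding pairs {excluded}"
            ) from exc
        omega = np.full(d, _OMEGA_FLOOR)
        omega[idx] = np.maximum(omega_sub, _OMEGA_FLOOR)
        flagged[idx] |= omega_sub < _OMEGA_FLOOR
        root = np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / (2.0 * root)
        np.clip(rho, -1.0, 1.0, out=rho)
        rho[~active_taxon, :] = np.nan
        rho[:, ~active_taxon] = np.nan
        np.fill_diagonal(rho, 1.0)
        return rho, omega

    rho, omega = solve()
    for _ in range(n_exclusion_iter):
        masked = np.where(np.isnan(rho), 0.0, np.abs(rho))
        np.fill_diagonal(masked, 0.0)
        masked[~active_pair] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        i, j = int(min(i, j)), int(max(i, j))
        excluded.append((i, j))
        active_pair[i, j] = active_pair[j, i] = False
        # drop taxa whose basis variance is no longer identifiable
        degrees = (active_pair & active_taxon[None, :]).sum(axis=1)
        for k in np.flatnonzero(active_taxon & (degrees < 3)):
            active_taxon[k] = False
            flagged[k] = True
            active_pair[k, :] = active_pair[:, k] = False
        if active_taxon.sum() < 4:
            break
        rho, omega = solve()
    return rho, omega, excluded, flagged


def sparcc_correlation(
    table: AsvTable | pd.DataFrame,
    n_inner_iter: int = 20,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> SparccResult:
    """Estimate basis correlations from a count table.

    Parameters follow the original algorithm's defaults: 20 Dirichlet
    fraction resamples averaged, up to 10 exclusion rounds at threshold 0.1.
    Requires at least 4 taxa (the basis system is ill-posed below).
    """
    counts = _counts_frame(table)
    x = counts.to_numpy(dtype=float)
    n, d = x.shape
    if d < 4:
        raise ValueError(f"SparCC needs >= 4 taxa (got {d})")
    if n_inner_iter < 0:
        raise ValueError("n_inner_iter must be >= 0")
    rng = np.random.default_rng(seed)
    alpha = x + pseudocount

    rho_sum = np.zeros((d, d))
    rho_count = np.zeros((d, d), dtype=np.int64)
    t_sum = np.zeros((d, d))
    omega_sum = np.zeros(d)
    exclusion_log: list[tuple[str, str]] = []
    clamped_any = np.zeros(d, dtype=bool)
    taxa = list(counts.columns)
    # n_inner_iter = 0 requests the deterministic plug-in fraction estimate
    # (posterior mean) instead of Dirichlet posterior resampling
    n_iter = max(1, n_inner_iter)
    for _ in range(n_iter):
        if n_inner_iter == 0:
            fracs = alpha / alpha.sum(axis=1, keepdims=True)
        else:
            # Dirichlet(counts + pseudocount) via normalized gammas, per sample
            g = rng.standard_gamma(alpha)
            fracs = g / g.sum(axis=1, keepdims=True)
        logf = np.log(fracs)
        v = np.cov(logf, rowvar=False)
        t = np.diag(v)[:, None] + np.diag(v)[None, :] - 2.0 * v
        np.fill_diagonal(t, 0.0)
        rho, omega, excluded, clamped = _basis_solution(
            t, n_exclusion_iter, exclusion_threshold
        )
        valid = ~np.isnan(rho)
        rho_sum[valid] += rho[valid]
        rho_count += valid
        t_sum += t
        omega_sum += omega
        clamped_any |= clamped
        for i, j in excluded:
            pair = (taxa[i], taxa[j])
            if pair not in exclusion_log:
                exclusion_log.append(pair)

    with np.errstate(invalid="ignore"):
        rho = np.where(rho_count > 0, rho_sum / np.maximum(rho_count, 1), np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    t_mean = t_sum / n_iter
    np.fill_diagonal(t_mean, 0.0)
    return SparccResult(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        t_var=pd.DataFrame(t_mean, index=taxa, columns=taxa),
        omega=pd.Series(omega_sum / n_iter, index=taxa, name="omega"),
        exclusion_log=exclusion_log,
        flagged=[taxa[i] for i in np.flatnonzero(clamped_any)],
        n_inner_iter=n_inner_iter,
        seed=seed if isinstance(seed, int) else None,
    )


def bootstrap_pvalues(
    table: AsvTable | pd.DataFrame,
    observed_rho: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    null: str = "permute",
    n_inner_iter: int = 20,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pseudo-p-values for SparCC correlations.

    ``null="permute"`` (default): each taxon's counts are permuted
    independently across samples per iteration and SparCC re-run; two-sided
    ``p = (#{|rho_null| >= |rho_obs|} + 1) / (n_boot + 1)``.

    ``null="bootstrap"``: samples are resampled with replacement and the
    p-value is the (bias-avoiding) fraction of resampled correlations whose
    sign contradicts the observed one — a sign-stability pseudo-p.

    The diagonal is 1 by convention.
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    if null not in ("permute", "bootstrap"):
        raise ValueError("null must be 'permute' or 'bootstrap'")
    counts = _counts_frame(table)
    if list(counts.columns) != list(observed_rho.columns):
        raise ValueError("observed_rho columns do not match table taxa")
    x = counts.to_numpy(dtype=np.int64)
    n, d = x.shape
    obs = np.abs(observed_rho.to_numpy())
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sparcc_seeds = ss.spawn(n_boot)

    hits = np.zeros((d, d))
    for b in range(n_boot):
        if null == "permute":
            resampled = np.empty_like(x)
            for k in range(d):
                resampled[:, k] = x[rng.permutation(n), k]
        else:
            resampled = x[rng.integers(0, n, size=n)]
        res = sparcc_correlation(
            pd.DataFrame(resampled, columns=counts.columns),
            n_inner_iter=n_inner_iter,
            n_exclusion_iter=n_exclusion_iter,
            exclusion_threshold=exclusion_threshold,
            pseudocount=pseudocount,
            seed=sparcc_seeds[b],
        )
        r = res.rho.to_numpy()
        if null == "permute":
            hits += np.where(np.isnan(r), 0, np.abs(r) >= obs)
        else:
            hits += np.where(np.isnan(r), 0, np.sign(r) != np.sign(observed_rho.to_numpy()))
    p = (hits + 1.0) / (n_boot + 1.0)
    p = np.minimum(p, 1.0)
    p = (p + p.T) / 2.0  # enforce symmetry against asymmetric tie handling
    p[np.isnan(obs)] = np.nan  # unidentifiable pairs carry no evidence
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=observed_rho.index, columns=observed_rho.columns)
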