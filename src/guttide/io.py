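"""Readers and writers for the pipeline's standard artifacts.

Tables travel as TSV, trees as newick, networks as GraphML.  Readers validate
eagerly and name the offending sample/ASV in error messages; id matching
across artifacts is exact string match, with an opt-in intersect mode so that
data loss is never silent.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    SITES,
    TAXONOMIC_RANKS,
    TIMEPOINTS,
    VFA_COMPONENTS,
    AsvTable,
    ValidationError,
)

__all__ = [
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "write_metadata",
    "read_covariates",
    "write_covariates",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_network",
    "write_network",
    "match_ids",
]


# ----------------------------------------------------------------- tables
def read_asv_table(path: str | Path, orientation: str = "samples") -> AsvTable:
    """Read a tab-separated count matrix.

    Parameters
    ----------
    orientation
        ``"samples"`` if rows are samples (samples × ASVs), ``"asvs"`` if rows
        are ASVs (the other convention in the wild); the table is transposed
        to the canonical samples × ASVs orientation.
    """
    if orientation not in ("samples", "asvs"):
        raise ValueError("orientation must be 'samples' or 'asvs'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "asvs":
        df = df.T
    return AsvTable(df)


def write_asv_table(table: AsvTable, path: str | Path) -> None:
    table.counts.rename_axis("sample_id").to_csv(path, sep="\t")


# --------------------------------------------------------------- metadata
def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, site, timepoint, animal_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = {"site", "timepoint", "animal_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if df.index.duplicated().any():
        raise ValidationError(
            f"duplicate sample ids in metadata: {list(df.index[df.index.duplicated()])[:5]}"
        )
    bad_site = df.loc[~df["site"].isin(SITES)]
    if len(bad_site):
        raise ValidationError(
            f"unknown site {bad_site['site'].iloc[0]!r} for sample "
            f"{bad_site.index[0]!r}; expected one of {SITES}"
        )
    bad_tp = df.loc[~df["timepoint"].isin(TIMEPOINTS)]
    if len(bad_tp):
        raise ValidationError(
            f"unknown timepoint {bad_tp['timepoint'].iloc[0]!r} for sample "
            f"{bad_tp.index[0]!r}; expected one of {TIMEPOINTS}"
        )
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("sample_id").to_csv(path, sep="\t")


# -------------------------------------------------------------- covariates
def read_covariates(path: str | Path, check_tvfa: bool = True) -> pd.DataFrame:
    """Read the covariate table (rumen VFAs and blood biochemistry)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_covariates(df, check_tvfa=check_tvfa)


def validate_covariates(df: pd.DataFrame, check_tvfa: bool = True, rtol: float = 0.01) -> pd.DataFrame:
    if df.index.duplicated().any():
        raise ValidationError("duplicate sample ids in covariate table")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite covariate {df.columns[c]!r} for sample {df.index[r]!r}"
        )
    if check_tvfa and "TVFA" in df.columns and all(v in df.columns for v in VFA_COMPONENTS):
        total = df[list(VFA_COMPONENTS)].sum(axis=1)
        off = ~np.isclose(df["TVFA"], total, rtol=rtol)
        if off.any():
            bad = df.index[off][0]
            raise ValidationError(
                f"TVFA inconsistent with VFA component sum for sample {bad!r} "
                f"({df.loc[bad, 'TVFA']:.4g} vs {total[bad]:.4g})"
            )
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------- taxonomy
def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = set(TAXONOMIC_RANKS) - set(df.columns)
    if missing:
        raise ValidationError(f"taxonomy missing ranks: {sorted(missing)}")
    if df.index.duplicated().any():
        raise ValidationError("duplicate ASV ids in taxonomy table")
    return df.fillna("unclassified")


def write_taxonomy(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("asv_id").to_csv(path, sep="\t")


# -------------------------------------------------------------------- tree
def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree and validate branch lengths and tip names."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"unparseable newick file {path}: {exc}") from exc
    return validate_tree(tree)


def parse_tree(newick: str) -> TreeNode:
    """Parse a newick string (convenience mirror of :func:`read_tree`)."""
    try:
        tree = TreeNode.read([newick], format="newick")
    except Exception as exc:
        raise ValidationError(f"unparseable newick: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValidationError("tree must have at least 2 tips")
    if len(set(tips)) != len(tips):
        raise ValidationError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            label = node.name or "internal node"
            raise ValidationError(f"missing branch length at {label}")
        if node.length < 0:
            raise ValidationError(f"negative branch length at {node.name or 'internal node'}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def patristic_matrix(tree: TreeNode, asv_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Tip-to-tip (patristic) distance matrix, optionally ordered/subset."""
    dm = tree.tip_tip_distances()
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    if asv_ids is not None:
        asv_ids = list(asv_ids)
        missing = [a for a in asv_ids if a not in df.index]
        if missing:
            raise ValidationError(f"ASVs missing from tree: {missing[:5]}")
        df = df.loc[asv_ids, asv_ids]
    return df


# ----------------------------------------------------------------- network
def write_network(network: nx.Graph, path: str | Path) -> None:
    """Write a correlation network as GraphML.

    Node attributes (phylum, module, role, degree) and edge attributes
    (r, p, sign) are rounded to 6 significant digits so round-trips are
    reproducible byte-for-byte.
    """
    g = network.copy()
    for _, data in g.nodes(data=True):
        data.setdefault("degree", 0)
        for key, val in list(data.items()):
            if isinstance(val, (float, np.floating)):
                data[key] = _round_sig(float(val))
            elif isinstance(val, (np.integer,)):
                data[key] = int(val)
    for _, _, data in g.edges(data=True):
        for key, val in list(data.items()):
            if isinstance(val, (float, np.floating)):
                data[key] = _round_sig(float(val))
    nx.write_graphml(g, str(path))


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def _round_sig(x: float, digits: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


# ------------------------------------------------------------- id matching
def match_ids(
    table: AsvTable,
    metadata: pd.DataFrame | None = None,
    tree: TreeNode | None = None,
    covariates: pd.DataFrame | None = None,
    intersect: bool = False,
) -> dict:
    """Cross-check ids between the count table and companion artifacts.

    By default mismatches raise; with ``intersect=True`` the table is
    restricted to the common ids and the dropped ids are reported.

    Returns a dict with the (possibly subset) table and a report of
    mismatches per artifact.
    """
    report: dict[str, dict] = {}
    samples = set(table.sample_ids)
    keep_samples = set(samples)
    if metadata is not None:
        meta_ids = set(metadata.index)
        report["metadata"] = {
            "samples_without_metadata": sorted(samples - meta_ids),
            "metadata_without_samples": sorted(meta_ids - samples),
        }
        keep_samples &= meta_ids
    if covariates is not None:
        cov_ids = set(covariates.index)
        report["covariates"] = {
            "samples_without_covariates": sorted(samples - cov_ids),
            "covariates_without_samples": sorted(cov_ids - samples),
        }
        keep_samples &= cov_ids
    keep_asvs = set(table.asv_ids)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        report["tree"] = {
            "asvs_not_in_tree": sorted(set(table.asv_ids) - tips),
            "tips_not_in_table": sorted(tips - set(table.asv_ids)),
        }
        keep_asvs &= tips

    mismatches = {
        k: v for k, v in report.items() if any(len(ids) > 0 for ids in v.values())
    }
    result_table = table
    if mismatches:
        if not intersect:
            lines = []
            for artifact, issues in mismatches.items():
                for kind, ids in issues.items():
                    if ids:
                        lines.append(f"{artifact}: {kind} = {ids[:5]}")
            raise ValidationError(
                "id mismatch between artifacts (pass intersect=True to keep "
                "the common subset):\n" + "\n".join(lines)
            )
        kept_sample_order = [s for s in table.sample_ids if s in keep_samples]
        kept_asv_order = [a for a in table.asv_ids if a in keep_asvs]
        if not kept_sample_order or not kept_asv_order:
            raise ValidationError("intersection of ids across artifacts is empty")
        result_table = AsvTable(table.counts.loc[kept_sample_order, kept_asv_order])
    return {"table": result_table, "report": report}
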