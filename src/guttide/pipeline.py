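"""End-to-end pipeline: config parsing, stage orchestration, reporting.

A single YAML config drives every stage (diversity → ordination/tests →
assembly → SparCC → network → association).  One global seed
deterministically spawns per-stage seeds, so identical configs yield
byte-identical numeric outputs.  Unknown config keys are rejected before
any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import diversity as div_mod
from . import network as net_mod
from .assembly import assembly_by_group
from .containers import SyntheticDataset
from .io import (
    match_ids,
    read_asv_table,
    read_covariates,
    read_metadata,
    read_taxonomy,
    read_tree,
    write_asv_table,
    write_covariates,
    write_metadata,
    write_network,
    write_taxonomy,
    write_tree,
)
from .simulate import SimulationConfig, simulate_communities
from .sparcc import bootstrap_pvalues, sparcc_correlation

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "write_simulated_bundle"]

_FLOAT_FMT = "%.6g"


# ------------------------------------------------------------------ config
@dataclass
class InputPaths:
    table: str
    metadata: str
    tree: str | None = None
    covariates: str | None = None
    taxonomy: str | None = None
    orientation: str = "samples"
    intersect: bool = False


@dataclass
class DiversityParams:
    pseudocount: float = 1.0
    n_perm: int = 999
    factors: tuple[str, ...] = ("site", "timepoint")


@dataclass
class AssemblyParams:
    n_null: int = 999
    by: str = "site"
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    weighted: bool = True


@dataclass
class SparccParams:
    n_inner_iter: int = 20
    n_exclusion_iter: int = 10
    exclusion_threshold: float = 0.1
    pseudocount: float = 1.0
    n_boot: int = 1000
    null: str = "permute"


@dataclass
class NetworkParams:
    min_prevalence: float = 0.5
    p_threshold: float = 0.01
    r_threshold: float = 0.6
    min_module_nodes: int = 20
    n_restarts: int = 10


@dataclass
class AssociationParams:
    level: str = "asv"
    min_mean_rel_abund: float = 1e-4
    min_frequency: float = 0.5
    family: str = "per_covariate"
    n_perm: int = 999
    n_axes: int = 2


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "guttide_out"
    inputs: InputPaths | None = None
    simulate: SimulationConfig | None = None
    diversity: DiversityParams = field(default_factory=DiversityParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    sparcc: SparccParams = field(default_factory=SparccParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    association: AssociationParams = field(default_factory=AssociationParams)

    def __post_init__(self) -> None:
        if self.inputs is None and self.simulate is None:
            self.simulate = SimulationConfig(seed=self.seed)
        if self.inputs is not None and self.simulate is not None:
            raise ValueError("config must give either 'inputs' or 'simulate', not both")


def _build(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            if f.name not in ("planted_pairs",):
                coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Parse a YAML file (or pre-parsed dict) into a validated config."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    sections = {
        "inputs": InputPaths,
        "simulate": SimulationConfig,
        "diversity": DiversityParams,
        "assembly": AssemblyParams,
        "sparcc": SparccParams,
        "network": NetworkParams,
        "association": AssociationParams,
    }
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in sections:
            kwargs[key] = _build(sections[key], value or {}, key)
        elif key in ("seed", "out_dir"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown top-level config key: {key!r}")
    if "simulate" in kwargs and "seed" in data and "seed" not in (data.get("simulate") or {}):
        kwargs["simulate"] = dataclasses.replace(kwargs["simulate"], seed=data["seed"])
    return PipelineConfig(**kwargs)


def _config_dict(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    return enc(config)


# ------------------------------------------------------------------ stages
def _load_inputs(paths: InputPaths):
    table = read_asv_table(paths.table, orientation=paths.orientation)
    metadata = read_metadata(paths.metadata)
    tree = read_tree(paths.tree) if paths.tree else None
    covariates = read_covariates(paths.covariates) if paths.covariates else None
    taxonomy = read_taxonomy(paths.taxonomy) if paths.taxonomy else None
    matched = match_ids(
        table, metadata=metadata, tree=tree, covariates=covariates,
        intersect=paths.intersect,
    )
    return matched["table"], tree, metadata, covariates, taxonomy


def write_simulated_bundle(dataset: SyntheticDataset, out: Path) -> None:
    """Write the TSV/newick artifacts plus the ground-truth JSON."""
    out.mkdir(parents=True, exist_ok=True)
    write_asv_table(dataset.table, out / "asv_table.tsv")
    write_metadata(dataset.metadata, out / "metadata.tsv")
    write_covariates(dataset.covariates, out / "covariates.tsv")
    write_taxonomy(dataset.taxonomy, out / "taxonomy.tsv")
    write_tree(dataset.tree, out / "tree.nwk")
    truth = {
        "regimes": dataset.truth.regimes,
        "planted_rho": [
            {"taxon_i": i, "taxon_j": j, "rho": r}
            for (i, j), r in dataset.truth.planted_rho.items()
        ],
        "covariate_loadings": dataset.truth.covariate_loadings.reset_index().to_dict(
            orient="records"
        ),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _write_df(df: pd.DataFrame, path: Path, index_name: str | None = None) -> None:
    if index_name:
        df = df.rename_axis(index_name)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and write the report bundle; returns the report dict."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_div, s_asm, s_sparcc, s_net, s_assoc = ss.spawn(5)
    report: dict[str, Any] = {
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
    }
    report["config_hash"] = hashlib.sha256(
        json.dumps(report["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    report["failed_stage"] = {"stage": name, "error": str(exc)}
                    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
                return False

        return _Timer()

    # ------------------------------------------------------------- inputs
    with stage("inputs"):
        if config.simulate is not None:
            dataset = simulate_communities(config.simulate)
            write_simulated_bundle(dataset, out / "inputs")
            table, tree = dataset.table, dataset.tree
            metadata, covariates, taxonomy = (
                dataset.metadata, dataset.covariates, dataset.taxonomy,
            )
        else:
            table, tree, metadata, covariates, taxonomy = _load_inputs(config.inputs)
        report["stages"]["inputs"] = {
            "n_samples": table.n_samples,
            "n_asvs": table.n_asvs,
            "simulated": config.simulate is not None,
        }

    # ---------------------------------------------------------- diversity
    with stage("diversity"):
        p = config.diversity
        alpha = div_mod.alpha_diversity(table)
        _write_df(alpha, out / "alpha_diversity.tsv")
        dist = div_mod.aitchison_distance(table, p.pseudocount)
        _write_df(
            pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids)),
            out / "aitchison_distance.tsv",
            "sample_id",
        )
        ordination = div_mod.pcoa(dist)
        _write_df(ordination.coordinates, out / "pcoa_coordinates.tsv", "sample_id")
        test_rows = []
        rng = np.random.default_rng(s_div)
        for factor in p.factors:
            fseed = int(rng.integers(0, 2**31 - 1))
            groups = metadata[factor]
            for test_fn in (div_mod.permanova, div_mod.anosim):
                res = test_fn(dist, groups, n_perm=p.n_perm, seed=fseed)
                test_rows.append({"factor": factor, **res.as_dict()})
            # pairwise Wilcoxon on each alpha metric
            levels = list(dict.fromkeys(groups))
            for metric in alpha.columns:
                for a_idx in range(len(levels)):
                    for b_idx in range(a_idx + 1, len(levels)):
                        ga, gb = levels[a_idx], levels[b_idx]
                        res = div_mod.wilcoxon_rank_sum(
                            alpha.loc[groups == ga, metric].dropna(),
                            alpha.loc[groups == gb, metric].dropna(),
                        )
                        test_rows.append(
                            {
                                "factor": factor,
                                "comparison": f"{metric}: {ga} vs {gb}",
                                **res.as_dict(),
                            }
                        )
        tests = pd.DataFrame(test_rows)
        _write_df(tests.set_index(tests.columns[0]), out / "group_tests.tsv")
        report["stages"]["diversity"] = {
            "mean_shannon_by_site": {
                site: round(float(alpha.loc[metadata["site"] == site, "shannon"].mean()), 4)
                for site in dict.fromkeys(metadata["site"])
            },
            "tests": [
                {k: row[k] for k in ("factor", "method", "statistic", "p_value")}
                for row in test_rows
                if "comparison" not in row
            ],
        }

    # ----------------------------------------------------------- assembly
    with stage("assembly"):
        p = config.assembly
        if tree is None:
            report["stages"]["assembly"] = {"skipped": "no tree provided"}
        else:
            results = assembly_by_group(
                table, tree, metadata, by=p.by, n_null=p.n_null, seed=s_asm,
                bnti_threshold=p.bnti_threshold, rc_threshold=p.rc_threshold,
                weighted=p.weighted,
            )
            frac_rows = []
            for level, res in results.items():
                _write_df(res.beta_nti, out / f"bnti_{level}.tsv", "sample_id")
                _write_df(res.rc_bray, out / f"rcbray_{level}.tsv", "sample_id")
                frac_rows.append(
                    {p.by: level, **res.fractions, "n_pairs": res.n_pairs,
                     "selection_combined": res.selection_fraction}
                )
            fractions = pd.DataFrame(frac_rows).set_index(p.by)
            _write_df(fractions, out / "assembly_fractions.tsv")
            report["stages"]["assembly"] = {
                level: {k: round(v, 4) for k, v in res.fractions.items()}
                for level, res in results.items()
            }

    # ----------------------------------------- sparcc + network (per site)
    with stage("network"):
        sp = config.sparcc
        np_ = config.network
        site_levels = list(dict.fromkeys(metadata["site"]))
        net_report = {}
        seeds = s_net.spawn(len(site_levels))
        sparcc_seeds = s_sparcc.spawn(2 * len(site_levels))
        for k, site in enumerate(site_levels):
            samples = [s for s in table.sample_ids if metadata.loc[s, "site"] == site]
            sub = table.subset_samples(samples)
            prevalent = net_mod.filter_prevalence(sub, np_.min_prevalence)
            res = sparcc_correlation(
                prevalent, n_inner_iter=sp.n_inner_iter,
                n_exclusion_iter=sp.n_exclusion_iter,
                exclusion_threshold=sp.exclusion_threshold,
                pseudocount=sp.pseudocount, seed=sparcc_seeds[2 * k],
            )
            pvals = bootstrap_pvalues(
                prevalent, res.rho, n_boot=sp.n_boot, seed=sparcc_seeds[2 * k + 1],
                null=sp.null, n_inner_iter=sp.n_inner_iter,
                n_exclusion_iter=sp.n_exclusion_iter,
                exclusion_threshold=sp.exclusion_threshold,
                pseudocount=sp.pseudocount,
            )
            _write_df(res.rho, out / f"sparcc_rho_{site}.tsv", "asv_id")
            _write_df(pvals, out / f"sparcc_p_{site}.tsv", "asv_id")
            graph = net_mod.build_network(
                res.rho, pvals, p_threshold=np_.p_threshold,
                r_threshold=np_.r_threshold, taxonomy=taxonomy,
            )
            metrics = net_mod.network_metrics(graph)
            if graph.number_of_edges() > 0:
                part_seed = int(np.random.default_rng(seeds[k]).integers(0, 2**31 - 1))
                partition, q = net_mod.louvain_modules(
                    graph, seed=part_seed, n_restarts=np_.n_restarts
                )
                major = net_mod.select_major_modules(partition, np_.min_module_nodes)
                roles = net_mod.classify_node_roles(graph, partition)
                for node, mid in partition.items():
                    graph.nodes[node]["module"] = int(mid)
                    role = roles.loc[node, "role"]
                    graph.nodes[node]["role"] = role if role else "unclassified"
                _write_df(roles, out / f"node_roles_{site}.tsv", "asv_id")
                metrics.update(
                    modularity=q, n_modules=len(set(partition.values())),
                    major_modules=major,
                    role_counts=roles["role"].value_counts().to_dict(),
                )
            write_network(graph, out / f"network_{site}.graphml")
            net_report[site] = {
                "n_prevalent_asvs": prevalent.n_asvs,
                **{k2: v for k2, v in metrics.items()},
            }
        (out / "network_metrics.json").write_text(
            json.dumps(net_report, indent=2, sort_keys=True, default=str)
        )
        report["stages"]["network"] = net_report

    # -------------------------------------------------------- association
    with stage("association"):
        ap = config.association
        if covariates is None:
            report["stages"]["association"] = {"skipped": "no covariates provided"}
        else:
            rng = np.random.default_rng(s_assoc)
            assoc_report = {}
            # covariate fit onto the all-sample ordination (site gradient)
            overall_ord = div_mod.pcoa(
                div_mod.aitchison_distance(table, config.diversity.pseudocount),
                n_axes=ap.n_axes,
            )
            ef_all = assoc_mod.envfit(
                overall_ord, covariates, n_perm=ap.n_perm,
                seed=int(rng.integers(0, 2**31 - 1)), n_axes=ap.n_axes,
            )
            _write_df(
                pd.concat([ef_all.directions, ef_all.r2, ef_all.p], axis=1),
                out / "envfit_overall.tsv", "covariate",
            )
            assoc_report["overall_envfit_top"] = (
                ef_all.r2.sort_values(ascending=False).head(3).round(3).to_dict()
            )
            for site in list(dict.fromkeys(metadata["site"])):
                samples = [s for s in table.sample_ids if metadata.loc[s, "site"] == site]
                sub = table.subset_samples(samples)
                cov_sub = covariates.loc[samples]
                at = assoc_mod.association_table(
                    sub, cov_sub, taxonomy=taxonomy, level=ap.level,
                    min_mean_rel_abund=ap.min_mean_rel_abund,
                    min_frequency=ap.min_frequency, family=ap.family,
                )
                _write_df(at.rho, out / f"association_rho_{site}.tsv", "taxon")
                _write_df(at.p, out / f"association_p_{site}.tsv", "taxon")
                _write_df(at.q, out / f"association_q_{site}.tsv", "taxon")
                site_dist = div_mod.aitchison_distance(sub, config.diversity.pseudocount)
                site_ord = div_mod.pcoa(site_dist, n_axes=ap.n_axes)
                ef = assoc_mod.envfit(
                    site_ord, cov_sub, n_perm=ap.n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)), n_axes=ap.n_axes,
                )
                ef_df = pd.concat([ef.directions, ef.r2, ef.p], axis=1)
                _write_df(ef_df, out / f"envfit_{site}.tsv", "covariate")
                assoc_report[site] = {
                    "n_taxa_tested": at.rho.shape[0],
                    "n_significant_q05": int((at.q.to_numpy() < 0.05).sum()),
                    "envfit_top": ef.r2.sort_values(ascending=False).head(3).round(3).to_dict(),
                }
            report["stages"]["association"] = assoc_report

    report["timings_s"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = [
        "# guttide pipeline report",
        "",
        f"- seed: {report['seed']}",
        f"- config hash: {report['config_hash']}",
        "",
    ]
    stages = report.get("stages", {})
    if "assembly" in stages and "skipped" not in stages["assembly"]:
        lines.append("## Assembly process fractions")
        lines.append("")
        for level, fr in stages["assembly"].items():
            parts = ", ".join(f"{k}={v:.1%}" for k, v in fr.items())
            lines.append(f"- **{level}**: {parts}")
        lines.append("")
    if "network" in stages:
        lines.append("## Network metrics")
        lines.append("")
        for site, m in stages["network"].items():
            lines.append(
                f"- **{site}**: {m.get('n_nodes', 0)} nodes, {m.get('n_edges', 0)} edges, "
                f"transitivity={m.get('transitivity', 0):.3f}"
            )
        lines.append("")
    lines.append("## Timings (s)")
    lines.append("")
    for name, t in report.get("timings_s", {}).items():
        lines.append(f"- {name}: {t}")
    lines.append("")
    return "\n".join(lines)
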