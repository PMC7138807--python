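"""Config-driven orchestration of the full analysis.

Stage order follows the survey workflow: ingest or synthesize -> rarefy to
even depth -> alpha diversity -> beta diversity (Bray-Curtis, weighted
UniFrac when a tree is present) -> geographic distances and distance-decay
(community-wide and per-phylum) -> Mantel environment-vs-geography screen
-> PERMANOVA / CAP on environmental covariates and ANOSIM on soil type ->
core microbiome (membership, partitioned Bray-Curtis contribution,
environment correlations) -> co-occurrence network (OTU and genus level,
Erdos-Renyi null, keystones, core/other contrast).

Every stochastic stage consumes a stage-named child seed derived from the
master seed, so any stage can be re-run in isolation and the whole bundle
is byte-reproducible from the manifest.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import core_contribution, core_env_correlations, find_core
from .diversity import alpha_diversity, bray_curtis, rarefy, weighted_unifrac
from .io import (OtuTable, SiteMetadata, read_metadata, read_newick,
                 read_otu_table, write_metadata, write_otu_table)
from .multivariate import anosim, cap, permanova
from .network import (aggregate_to_genus, build_network, compare_core_subnetworks,
                      correlation_matrix, er_null_ensemble, keystone_taxa,
                      topology, write_edge_list, write_graphml)
from .spatial import ddr_by_phylum, ddr_fit, haversine_matrix, mantel
from .synth import SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "ResultsBundle", "PipelineError", "run_pipeline", "child_seed"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the master seed."""
    return int(np.random.SeedSequence(
        [int(master), zlib.crc32(stage.encode())]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    # inputs: either file paths or a synthetic generator config
    otu_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    synthetic: SyntheticConfig | None = None
    rarefaction: str = "min"          # "min" or a fixed integer depth
    beta_metric: str = "braycurtis"   # DDR dissimilarity: braycurtis | unifrac
    r_min: float = 0.6
    q_max: float = 0.01
    core_prevalence: float = 1.0
    keystone_k: int = 7
    n_perm: int = 999
    er_replicates: int = 10
    per_phylum_ddr: bool = True
    env_terms: tuple[str, ...] = ("PRE", "pH")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.core_prevalence <= 1):
            raise ValueError("core_prevalence must be in (0, 1]")
        if not (0 <= self.r_min <= 1) or not (0 < self.q_max <= 1):
            raise ValueError("network thresholds out of range")
        if self.synthetic is None and (self.otu_table is None or self.metadata is None):
            raise ValueError("either synthetic config or input paths required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("env_covariates", "lat_range", "lon_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "env_terms" in raw:
            raw["env_terms"] = tuple(raw["env_terms"])
        return cls(**raw)


@dataclass
class ResultsBundle:
    out_dir: Path
    results: dict
    manifest: dict


def _frame(obj) -> pd.DataFrame:
    return obj.to_dataframe() if hasattr(obj, "to_dataframe") else pd.DataFrame(obj)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ResultsBundle:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    artifacts: list[str] = []

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        frame.to_csv(out / name, sep="\t", index=index, lineterminator="\n")
        artifacts.append(name)

    # -- ingest / synthesize ------------------------------------------------
    stage = "ingest"
    try:
        if config.synthetic is not None:
            syn = config.synthetic
            metadata, table, tree, truth = generate_dataset(syn)
            write_otu_table(table, out / "otu_table.tsv")
            write_metadata(metadata, out / "metadata.tsv")
            tree.write(str(out / "tree.nwk"))
            truth.to_json(out / "truth.json")
            artifacts += ["otu_table.tsv", "metadata.tsv", "tree.nwk", "truth.json"]
        else:
            table = read_otu_table(config.otu_table)
            metadata = read_metadata(config.metadata)
            tree = read_newick(config.tree) if config.tree else None
        if list(metadata.sample_ids) != list(table.sample_ids):
            metadata_order = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
            if len(metadata_order) != table.n_samples:
                raise ValueError("metadata does not cover all table samples")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    # -- rarefaction --------------------------------------------------------
    def _rarefy():
        depth = None if config.rarefaction == "min" else int(config.rarefaction)
        rare = rarefy(table, depth, seed=child_seed(config.seed, "rarefy"))
        write_otu_table(rare, out / "otu_table_rarefied.tsv")
        artifacts.append("otu_table_rarefied.tsv")
        results["rarefaction_depth"] = int(rare.sample_totals()[0])
        return rare
    rare = run_stage("rarefy", _rarefy)

    # -- alpha diversity ----------------------------------------------------
    def _alpha():
        alpha = alpha_diversity(rare)
        emit("alpha_diversity.tsv", alpha.to_dataframe())
        results["alpha"] = {"mean_richness": float(np.mean(alpha.richness)),
                            "mean_shannon": float(np.mean(alpha.shannon))}
        return alpha
    run_stage("alpha", _alpha)

    # -- beta diversity -----------------------------------------------------
    def _beta():
        bc = bray_curtis(rare, on="relative")
        bc.to_tsv(out / "bray_curtis.tsv")
        artifacts.append("bray_curtis.tsv")
        wu = None
        if tree is not None:
            wu = weighted_unifrac(rare, tree, normalized=True)
            wu.to_tsv(out / "weighted_unifrac.tsv")
            artifacts.append("weighted_unifrac.tsv")
        return bc, wu
    bc, wu = run_stage("beta", _beta)
    dissim = wu if (config.beta_metric == "unifrac" and wu is not None) else bc

    # -- spatial ------------------------------------------------------------
    def _spatial():
        geo = haversine_matrix(metadata)
        geo.to_tsv(out / "geographic_km.tsv")
        artifacts.append("geographic_km.tsv")
        fit = ddr_fit(geo, dissim)
        ddr_rows = [{"scope": "community", "slope": fit.slope, "intercept": fit.intercept,
                     "p_value": fit.p_value, "r_squared": fit.r_squared,
                     "n_pairs": fit.n_pairs}]
        if config.per_phylum_ddr and table.lineages is not None:
            phyla = sorted({l.phylum for l in table.lineages if l.phylum})
            for ph in phyla:
                try:
                    pfit = ddr_by_phylum(rare, geo, ph)
                except ValueError:
                    continue
                ddr_rows.append({"scope": ph, "slope": pfit.slope,
                                 "intercept": pfit.intercept, "p_value": pfit.p_value,
                                 "r_squared": pfit.r_squared, "n_pairs": pfit.n_pairs})
        emit("ddr_fits.tsv", pd.DataFrame(ddr_rows), index=False)
        results["ddr"] = ddr_rows
        env_num = metadata.env.select_dtypes("number")
        from scipy.spatial.distance import pdist, squareform
        env_d = squareform(pdist((env_num - env_num.mean()) / env_num.std(), "euclidean"))
        from .diversity import DistanceMatrix
        mr = mantel(geo, DistanceMatrix(list(metadata.sample_ids), env_d, "env"),
                    n_perm=config.n_perm, seed=child_seed(config.seed, "mantel"))
        results["mantel_env_geo"] = {"r": mr.statistic, "p": mr.p_value,
                                     "method": mr.method}
        return geo
    geo = run_stage("spatial", _spatial)

    # -- multivariate -------------------------------------------------------
    def _multivariate():
        design = metadata.env[list(config.env_terms)]
        perm = permanova(dissim, design, n_perm=config.n_perm,
                         seed=child_seed(config.seed, "permanova"))
        _, cap_test = cap(dissim, design, n_perm=config.n_perm,
                          seed=child_seed(config.seed, "cap"))
        results["permanova"] = [t.__dict__ for t in perm]
        results["cap"] = cap_test.__dict__
        if metadata.soil_type is not None:
            counts = pd.Series(metadata.soil_type).value_counts()
            usable = counts[counts >= 2].index
            keep = [s for s, t in zip(metadata.sample_ids, metadata.soil_type)
                    if t in set(usable)]
            if len(set(t for t in metadata.soil_type if t in set(usable))) >= 2:
                sub = dissim.reorder(keep)
                groups = [t for t in metadata.soil_type if t in set(usable)]
                an = anosim(sub, groups, n_perm=config.n_perm,
                            seed=child_seed(config.seed, "anosim"))
                results["anosim_soil_type"] = {"R": an.statistic, "p": an.p_value}
    run_stage("multivariate", _multivariate)

    # -- core microbiome ----------------------------------------------------
    def _core():
        core = find_core(rare, config.core_prevalence)
        pd.Series(core.core_otu_ids, name="otu_id").to_csv(
            out / "core_otus.tsv", sep="\t", index=False, lineterminator="\n")
        artifacts.append("core_otus.tsv")
        contrib = core_contribution(rare, core, on="counts")
        emit("core_contribution.tsv", contrib.to_dataframe(), index=False)
        results["core"] = {
            "n_core": len(core),
            "core_fraction_percent": 100.0 * len(core) / rare.n_otus,
            "contribution_mean_percent": 100.0 * contrib.mean_fraction,
            "contribution_range_percent": [100.0 * v for v in contrib.fraction_range],
        }
        if core.genera:
            masked, _full = core_env_correlations(rare, core, metadata,
                                                  r_min=config.r_min, alpha=0.05)
            emit("core_env_correlations.tsv", masked)
        return core
    core = run_stage("core", _core)

    # -- co-occurrence network ---------------------------------------------
    def _network():
        lineage_map = (dict(zip(rare.otu_ids, rare.lineages))
                       if rare.lineages is not None else None)
        r, p, dropped = correlation_matrix(rare)
        net = build_network(r, p, r_min=config.r_min, q_max=config.q_max,
                            lineages=lineage_map, core_ids=set(core.core_otu_ids))
        write_graphml(net, out / "network_otu.graphml")
        write_edge_list(net, out / "network_otu_edges.tsv")
        artifacts.extend(["network_otu.graphml", "network_otu_edges.tsv"])
        topo = topology(net)
        results["network_otu"] = topo.__dict__
        results["network_otu"]["n_zero_variance_dropped"] = len(dropped)
        if net.number_of_edges() > 0:
            null = er_null_ensemble(net.number_of_nodes(), net.number_of_edges(),
                                    n_reps=config.er_replicates,
                                    seed=child_seed(config.seed, "er_null"))
            results["er_null"] = {
                "n_replicates": config.er_replicates,
                "modal_diameter": null.modal_diameter,
                "mean_apl": float(np.mean([t.average_path_length for t in null.replicates])),
                "mean_clustering": float(np.mean([t.clustering for t in null.replicates])),
            }
        if rare.lineages is not None:
            genus_table = aggregate_to_genus(rare)
            gr, gp, _ = correlation_matrix(genus_table)
            core_genera = set(core.genera)
            gnet = build_network(gr, gp, r_min=config.r_min, q_max=config.q_max,
                                 lineages=dict(zip(genus_table.otu_ids, genus_table.lineages)),
                                 core_ids=core_genera)
            write_graphml(gnet, out / "network_genus.graphml")
            artifacts.append("network_genus.graphml")
            results["network_genus"] = topology(gnet).__dict__
            if gnet.number_of_nodes() >= 3:
                k = min(config.keystone_k, gnet.number_of_nodes())
                report = keystone_taxa(gnet, k)
                emit("keystone_genera.tsv", report.table)
                results["keystones"] = report.keystones
                others = set(gnet.nodes) - core_genera
                if core_genera & set(gnet.nodes) and others:
                    tc, to, (w_stat, w_p) = compare_core_subnetworks(gnet, core_genera)
                    results["core_vs_other"] = {
                        "core_topology": tc.__dict__, "other_topology": to.__dict__,
                        "wilcoxon_statistic": w_stat, "wilcoxon_p": w_p,
                    }
    run_stage("network", _network)

    # -- bundle -------------------------------------------------------------
    (out / "results.json").write_text(json.dumps(results, indent=1, default=float))
    artifacts.append("results.json")
    manifest = {
        "soilbiogeo_version": __version__,
        "seed": config.seed,
        "config": {k: (asdict(v) if isinstance(v, SyntheticConfig) else v)
                   for k, v in asdict(config).items()},
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return ResultsBundle(out, results, manifest)
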