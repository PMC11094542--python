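"""Config-driven orchestration of the full analysis chain.

One :class:`RunConfig` (flat key-value mapping, YAML on disk) drives:
simulate (optional) -> community structure -> enzyme stoichiometry ->
assembly partitioning (whole / abundant / rare) -> co-occurrence network.
Every stage writes TSV outputs plus one machine-readable ``summary.json``;
re-running the same config and seed reproduces the numbers exactly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import community_structure as cs
from . import enzyme_stoich as es
from . import network as netmod
from . import synthetic_data as synth
from .io_core import (Bundle, read_asv_table, read_enzymes, read_metadata,
                      read_taxonomy, read_tree, resolve_bundle)

log = logging.getLogger("crust_assembly")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    # inputs: either file paths ...
    table_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    enzymes_path: str | None = None
    # ... or a simulation spec
    simulate: bool = False
    regime: str = "neutral"
    n_samples: int = 12
    depth: int = 2000
    n_taxa: int = 150
    limitation: str = "balanced"
    noise_sd: float = 0.05
    # stage toggles
    run_structure: bool = True
    run_enzymes: bool = True
    run_assembly: bool = True
    run_network: bool = True
    # thresholds and sizes
    rare_cut: float = 0.001
    abund_cut: float = 0.01
    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    t_min: float = 0.30
    t_max: float = 0.90
    t_step: float = 0.01
    prevalence: float = 0.25
    subsets: tuple = ("whole", "abundant", "rare")
    mantel_variables: tuple = ("pH", "SOC", "C_N", "C_P")
    n_null: int = 999
    n_perm: int = 999
    n_rewire_null: int = 50
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if not (0 < self.rare_cut < self.abund_cut < 1):
            raise ValueError("need 0 < rare_cut < abund_cut < 1")
        if not (0 < self.rc_cut <= 1):
            raise ValueError("rc_cut must be in (0, 1]")
        if self.bnti_cut <= 0:
            raise ValueError("bnti_cut must be > 0")
        if not (0 < self.t_min < self.t_max <= 1):
            raise ValueError("need 0 < t_min < t_max <= 1")
        if self.n_null < 1 or self.n_perm < 1:
            raise ValueError("n_null and n_perm must be >= 1")
        if not self.simulate and not all((self.table_path, self.taxonomy_path,
                                          self.tree_path, self.metadata_path,
                                          self.enzymes_path)):
            raise ValueError("either simulate=true or all five input paths")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("subsets", "mantel_variables"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _load_bundle(config: RunConfig, out: Path) -> Bundle:
    if config.simulate:
        spec = synth.default_regime_spec(
            config.regime, n_samples=config.n_samples, depth=config.depth,
            n_taxa=config.n_taxa, seed=config.seed)
        sbundle = synth.make_bundle(spec, config.limitation, config.noise_sd)
        synth.write_bundle(sbundle, out / "inputs")
        return sbundle.as_bundle()
    bundle = Bundle(
        table=read_asv_table(config.table_path),
        taxonomy=read_taxonomy(config.taxonomy_path),
        tree=read_tree(config.tree_path),
        metadata=read_metadata(config.metadata_path),
        enzymes=read_enzymes(config.enzymes_path),
    )
    return resolve_bundle(bundle)


def _assembly_stage(config: RunConfig, bundle: Bundle, partition, out: Path) -> dict:
    dist = bundle.tree.patristic_distances(bundle.table.asv_ids)
    section: dict = {}
    subset_ids = {
        "whole": bundle.table.asv_ids,
        "abundant": sorted(partition.abundant),
        "rare": sorted(partition.rare),
    }
    for subset in config.subsets:
        ids = subset_ids[subset]
        if len(ids) < 2:
            log.warning("subset %s has <2 taxa; skipped", subset)
            continue
        sub = bundle.table.subset_asvs(ids)
        keep = sub.data.sum(axis=1) > 0
        sub = type(sub)(sub.data.loc[keep], is_relative=False)
        pairs = asm.pairwise_assembly(
            sub, dist.loc[ids, ids], n_null=config.n_null, seed=config.seed,
            bnti_cut=config.bnti_cut, rc_cut=config.rc_cut)
        pairs.to_csv(out / f"assembly_pairs_{subset}.tsv", sep="\t", index=False)
        summary = asm.assembly_summary(pairs)
        summary.to_csv(out / f"assembly_fractions_{subset}.tsv", sep="\t")
        section[subset] = {"fractions": summary.loc["all"].to_dict()}

        bnti_mat = pd.DataFrame(0.0, index=sub.sample_ids, columns=sub.sample_ids)
        for _, row in pairs.iterrows():
            bnti_mat.loc[row.sample_a, row.sample_b] = row.bnti
            bnti_mat.loc[row.sample_b, row.sample_a] = row.bnti
        mantels = {}
        if bnti_mat.notna().values.all() and np.nanstd(bnti_mat.values) > 0:
            for var in config.mantel_variables:
                env = asm.env_distance(bundle.metadata, var, samples=sub.sample_ids)
                try:
                    res = asm.mantel(bnti_mat, env, n_perm=config.n_perm,
                                     seed=config.seed, variable=var)
                    mantels[var] = {"r": res.r, "p": res.p}
                except ValueError as exc:
                    mantels[var] = {"error": str(exc)}
        section[subset]["mantel_bnti_vs_env"] = mantels
        section[subset]["n_pairs"] = int(len(pairs))
    return section


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the JSON-ready run summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in dataclasses.asdict(config).items()},
                     "seed": config.seed}

    stage = "load"
    try:
        bundle = _load_bundle(config, out)
        rel = cs.to_relative(bundle.table)
        partition = cs.partition_taxa(rel, config.rare_cut, config.abund_cut)

        if config.run_structure:
            stage = "structure"
            partition.as_frame().to_csv(out / "taxon_partition.tsv", sep="\t")
            shannon = cs.shannon_index(bundle.table)
            shannon.to_csv(out / "shannon.tsv", sep="\t")
            ratio = cs.copiotroph_ratio(rel, bundle.taxonomy)
            ratio.to_csv(out / "copiotroph_ratio.tsv", sep="\t")
            bc = cs.bray_curtis_matrix(rel)
            bc.to_csv(out / "bray_curtis.tsv", sep="\t")
            ord_res = cs.pcoa(bc, k=2)
            ord_res.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
            sites = bundle.metadata.sites.loc[rel.sample_ids]
            perm = None
            if sites.nunique() >= 2 and sites.value_counts().min() >= 2:
                perm = cs.permanova(bc, sites, n_perm=config.n_perm, seed=config.seed)
                (out / "permanova.json").write_text(json.dumps(vars(perm), indent=2))
            summary["structure"] = {
                "n_abundant": len(partition.abundant),
                "n_rare": len(partition.rare),
                "n_intermediate": len(partition.intermediate),
                "shannon_mean": float(shannon.mean()),
                "copiotroph_ratio_mean": float(ratio.mean()),
                "pcoa_prop_explained": [float(v) for v in ord_res.proportion_explained],
                "permanova": vars(perm) if perm else None,
            }

        if config.run_enzymes:
            stage = "enzymes"
            enz = es.enzyme_summary(bundle.enzymes)
            enz.to_csv(out / "enzyme_summary.tsv", sep="\t")
            summary["enzymes"] = {
                "mean_angle_deg": float(enz["angle_deg"].mean()),
                "mean_length": float(enz["length"].mean()),
                "vector_calls": enz["vector_call"].value_counts().to_dict(),
                "quadrant_calls": enz["quadrant"].value_counts().to_dict(),
            }

        if config.run_assembly:
            stage = "assembly"
            summary["assembly"] = _assembly_stage(config, bundle, partition, out)

        if config.run_network:
            stage = "network"
            filtered = netmod.prevalence_filter(bundle.table, config.prevalence)
            corr = netmod.correlation_matrix(filtered)
            t_grid = np.round(np.arange(config.t_min, config.t_max + 1e-9,
                                        config.t_step), 10)
            try:
                thr = netmod.rmt_threshold(corr, t_grid=t_grid)
            except ValueError as exc:
                log.warning("RMT threshold failed (%s); using t_max", exc)
                thr = config.t_max
            net = netmod.build_network(corr, thr)
            pd.DataFrame(net.edges, columns=["asv_a", "asv_b", "r"]).to_csv(
                out / "network_edges.tsv", sep="\t", index=False)
            topo = netmod.topology(net, n_rewire_null=config.n_rewire_null,
                                   seed=config.seed)
            (out / "network_topology.json").write_text(
                json.dumps(topo.as_dict(), indent=2))
            net_section = {"threshold": thr, "topology": topo.as_dict()}
            if net.graph.number_of_edges() >= 1:
                mods = netmod.modules(net, partition)
                pd.Series(mods.membership, name="module").to_csv(
                    out / "network_modules.tsv", sep="\t")
                comp = netmod.sample_complexity(net, filtered)
                comp.scores.to_csv(out / "network_complexity.tsv", sep="\t")
                ratios = es.stoich_ratios(bundle.enzymes)
                rels = {}
                for which in ("cn", "cp"):
                    try:
                        rels[which] = netmod.complexity_vs_ratio(comp, ratios, which)
                    except ValueError as exc:
                        rels[which] = {"error": str(exc)}
                net_section.update({
                    "n_modules": len(mods.sizes),
                    "module_sizes": mods.sizes,
                    "complexity_vs_ratio": rels,
                })
            summary["network"] = net_section
    except Exception as exc:
        log.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["runtime_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
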