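"""Synthetic communities with known assembly ground truth.

Emulates the five pipeline inputs without any sequencing data: a Yule
phylogeny, Brownian-motion environmental optima on that phylogeny (so that
selection regimes leave a phylogenetic imprint), lognormal metacommunity
abundances sampled into per-sample multinomial counts under one of five named
assembly regimes, and soil metadata / enzyme activities with a configurable
nutrient-limitation scenario.

Regimes and the pairwise signatures they are built to produce
(thresholds |betaNTI| = 2, |RC_bray| = 0.95):

==========================  ==============================================
homogeneous_selection       identical environment, strong filtering on
                            phylogenetically conserved optima -> betaNTI < -2
heterogeneous_selection     widely spread environments -> betaNTI > +2
dispersal_limitation        independent small taxon pools per sample with
                            sample-specific dominance -> |betaNTI| <= 2,
                            RC_bray > +0.95
homogenizing_dispersal      every sample resampled from one shared realized
                            community -> RC_bray < -0.95
neutral                     plain metacommunity sampling -> both metrics null
==========================  ==============================================
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_core import (
    AsvTable, EnzymeActivities, PhylogeneticTree, SampleMetadata,
    TaxonomyTable, Bundle, ENZYME_COLUMNS, SOIL_VARIABLES,
)

__all__ = [
    "RegimeSpec", "SyntheticBundle", "REGIMES",
    "simulate_tree", "simulate_optima_bm", "simulate_communities",
    "simulate_soil_enzymes", "default_regime_spec", "make_bundle",
    "write_bundle", "bundle_from_truth",
]

REGIMES = (
    "homogeneous_selection", "heterogeneous_selection",
    "dispersal_limitation", "homogenizing_dispersal", "neutral",
)

#: ten phyla with a declared copiotroph/oligotroph split (synthetic stand-in
#: for a literature-derived life-strategy annotation)
SYNTHETIC_PHYLA = {
    "Proteobacteria": "copiotroph",
    "Bacteroidota": "copiotroph",
    "Firmicutes": "copiotroph",
    "Actinobacteriota": "copiotroph",
    "Gemmatimonadota": "copiotroph",
    "Acidobacteriota": "oligotroph",
    "Chloroflexi": "oligotroph",
    "Verrucomicrobiota": "oligotroph",
    "Planctomycetota": "oligotroph",
    "Nitrospirota": "oligotroph",
}

# site-like baselines for the ten soil variables (karst topsoil scale)
_SOIL_BASELINES = {
    "pH": 7.5, "EC": 160.0, "SWC": 12.0, "SOC": 45.0, "TN": 4.0,
    "NH4_N": 40.0, "NO3_N": 15.0, "TP": 0.8, "AP_avail": 40.0, "AK": 250.0,
}

# enzyme baselines per limitation scenario; chosen so the expected stoichiometry
# vector angle is < 45 deg (N), > 45 deg (P) or exactly 45 deg (balanced):
# angle = atan(Y/X) with X = (BG+CB)/(BG+CB+AP), Y = (BG+CB)/(BG+CB+NAG+LAP)
_ENZYME_BASELINES = {
    "balanced": {"AG": 12.0, "BG": 40.0, "XS": 18.0, "CB": 15.0,
                 "NAG": 20.0, "LAP": 10.0, "AP": 30.0},
    "N":        {"AG": 12.0, "BG": 40.0, "XS": 18.0, "CB": 15.0,
                 "NAG": 30.0, "LAP": 15.0, "AP": 20.0},
    "P":        {"AG": 12.0, "BG": 40.0, "XS": 18.0, "CB": 15.0,
                 "NAG": 13.0, "LAP": 7.0, "AP": 45.0},
}


def _child_seed(seed: int, stage: int) -> int:
    """Expand one global seed into per-stage child seeds by fixed offsets."""
    return int((int(seed) * 100003 + 7919 * stage) % (2 ** 31))


@dataclass
class RegimeSpec:
    """Parameters of one simulated community-assembly scenario."""

    regime: str
    n_samples: int = 12
    depth: int = 1000
    n_taxa: int = 800
    selection_strength: float = 100.0
    env_values: Sequence[float] | None = None
    seed: int = 0
    sad_sigma: float = 1.5          # lognormal species-abundance spread
    bm_sigma: float = 1.0           # Brownian-motion rate for optima
    trait_depth_power: float = 0.5  # <1: optima conserved at clade level
    pool_fraction: float = 0.2      # dispersal_limitation: per-sample pool size

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.env_values is not None:
            self.env_values = [float(v) for v in self.env_values]
            if len(self.env_values) != self.n_samples:
                raise ValueError("env_values length must equal n_samples")


def default_regime_spec(regime: str, **overrides) -> RegimeSpec:
    """Spec with regime-appropriate default environments filled in."""
    spec = RegimeSpec(regime=regime, **overrides)
    if spec.env_values is None and regime == "homogeneous_selection":
        spec.env_values = [0.0] * spec.n_samples
    if spec.env_values is None and regime == "heterogeneous_selection":
        spec.env_values = list(np.linspace(-1.5, 1.5, spec.n_samples))
    return spec


# ---------------------------------------------------------------------------
# tree + trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, backbone_fraction: float = 0.8,
                  backbone_depth: float = 0.95) -> PhylogeneticTree:
    """Pure-birth (Yule) ultrametric tree, rescaled to root depth exactly 1.

    Waiting times between speciation events are exponential with rate equal to
    the number of extant lineages (per-lineage birth rate 1); a final
    exponential stub separates the last speciation from the present.

    Node depths are then warped by a piecewise-linear time rescaling that
    stretches the first `backbone_fraction` of the timeline over
    `backbone_depth` of the final depth, compressing the remaining splits into
    shallow terminal radiations.  This mimics marker-gene (16S) phylogenies,
    where exact sequence variants sit in tight clusters hanging off deep
    backbone branches; `backbone_fraction=backbone_depth` disables the warp
    and yields a plain Yule clock.  The result stays ultrametric with root
    depth exactly 1.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (0 < backbone_fraction < 1 and 0 < backbone_depth < 1):
        raise ValueError("backbone parameters must be in (0, 1)")
    rng = np.random.default_rng(seed)

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    # the root is the first split at time 0, so every tip sits at depth t
    birth_time: dict[int, float] = {}
    active = []
    for _ in range(2):
        child = root.new_child()
        birth_time[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        for _ in range(2):
            child = node.new_child()
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / n_tips)

    b, gb = backbone_fraction, backbone_depth

    def warp(d: float) -> float:
        # piecewise-linear time rescaling: [0, b] -> [0, gb], [b, 1] -> [gb, 1]
        return d * gb / b if d <= b else gb + (d - b) * (1 - gb) / (1 - b)

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        kids = node.child_nodes()
        end = birth_time[id(kids[0])] if kids else t
        node.edge.length = (warp(end / t) - warp(birth_time[id(node)] / t))

    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(label=f"ASV{i + 1:0{width}d}")
    return PhylogeneticTree(tree)


def simulate_optima_bm(tree: PhylogeneticTree, sigma: float, seed: int,
                       depth_power: float = 1.0) -> pd.Series:
    """Brownian-motion environmental optima along branches, root value 0.

    With the default `depth_power=1` a tip's variance is sigma^2 times its
    root-to-tip length.  `depth_power < 1` accumulates the variance along
    power-transformed node depths (a Pagel-delta-style transform), pushing
    trait divergence onto deep branches so that the optimum behaves as a
    clade-conserved niche rather than a tip-level trait; total tip variance on
    a depth-1 tree is sigma^2 either way.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if depth_power <= 0:
        raise ValueError("depth_power must be > 0")
    rng = np.random.default_rng(seed)
    depth: dict[int, float] = {id(tree.tree.seed_node): 0.0}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            d0, d1 = depth[id(node.parent_node)], depth[id(node)]
            var = max(d1 ** depth_power - d0 ** depth_power, 0.0)
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, sigma * np.sqrt(var))
        if not node.child_nodes():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="optimum")


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

def simulate_communities(spec: RegimeSpec, tree: PhylogeneticTree,
                         optima: pd.Series | None = None,
                         ) -> tuple[AsvTable, pd.Series]:
    """Sample count communities under the regime; returns (table, tip optima).

    The metacommunity species-abundance distribution is lognormal(0, sad_sigma)
    over the first `n_taxa` tree tips.  Selection regimes weight each taxon by
    exp(-selection_strength * (optimum - env)^2); dispersal limitation draws an
    independent small taxon pool per sample and re-draws that sample's relative
    abundances (ecological drift); homogenizing dispersal resamples every
    sample from one shared realized community.
    """
    if tree.n_tips < spec.n_taxa:
        raise ValueError(f"tree has {tree.n_tips} tips < n_taxa={spec.n_taxa}")
    taxa = tree.tip_labels[: spec.n_taxa]
    rng = np.random.default_rng(_child_seed(spec.seed, 2))

    if optima is None:
        optima = simulate_optima_bm(tree, spec.bm_sigma, _child_seed(spec.seed, 1),
                                    depth_power=spec.trait_depth_power)
    optima = optima.loc[taxa]

    meta = rng.lognormal(0.0, spec.sad_sigma, spec.n_taxa)
    meta /= meta.sum()

    selection = spec.regime in ("homogeneous_selection", "heterogeneous_selection")
    if selection and spec.env_values is None:
        raise ValueError(f"regime {spec.regime!r} requires env_values")

    counts = np.zeros((spec.n_samples, spec.n_taxa), dtype=int)
    if selection:
        env = np.asarray(spec.env_values, dtype=float)
        for s in range(spec.n_samples):
            w = meta * np.exp(-spec.selection_strength * (optima.values - env[s]) ** 2)
            if w.sum() == 0:
                raise ValueError("selection weights underflowed to zero")
            counts[s] = rng.multinomial(spec.depth, w / w.sum())
    elif spec.regime == "dispersal_limitation":
        k = max(2, int(round(spec.pool_fraction * spec.n_taxa)))
        for s in range(spec.n_samples):
            pool = rng.choice(spec.n_taxa, size=k, replace=False)
            w = np.zeros(spec.n_taxa)
            w[pool] = rng.lognormal(0.0, spec.sad_sigma, k)  # local drift
            counts[s] = rng.multinomial(spec.depth, w / w.sum())
    elif spec.regime == "homogenizing_dispersal":
        shared = rng.multinomial(spec.depth, meta).astype(float)
        shared /= shared.sum()
        for s in range(spec.n_samples):
            counts[s] = rng.multinomial(spec.depth, shared)
    else:  # neutral
        for s in range(spec.n_samples):
            counts[s] = rng.multinomial(spec.depth, meta)

    samples = [f"S{str(i + 1).zfill(2)}" for i in range(spec.n_samples)]
    table = AsvTable(pd.DataFrame(counts, index=samples, columns=taxa))
    return table, optima


# ---------------------------------------------------------------------------
# soil + enzyme simulation
# ---------------------------------------------------------------------------

def simulate_soil_enzymes(table: AsvTable, limitation: str = "balanced",
                          noise_sd: float = 0.05, seed: int = 0,
                          sites: Sequence[str] | None = None,
                          ) -> tuple[SampleMetadata, EnzymeActivities]:
    """Soil metadata and enzyme activities with a known limitation scenario.

    Enzyme baselines are constructed so the expected stoichiometry-vector angle
    sits below / above / exactly at 45 degrees for N / P / balanced limitation;
    multiplicative lognormal noise of scale `noise_sd` jitters every value.
    """
    if limitation not in _ENZYME_BASELINES:
        raise ValueError(f"unknown limitation {limitation!r}; "
                         f"choose from {sorted(_ENZYME_BASELINES)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(_child_seed(seed, 3))
    samples = table.sample_ids
    n = len(samples)

    if sites is None:
        thirds = int(np.ceil(n / 3))
        sites = (["A"] * thirds + ["B"] * thirds + ["C"] * thirds)[:n]
    site_factor = {name: f for name, f in zip(sorted(set(sites)), (1.0, 1.2, 0.85))}

    meta_rows = {}
    for s, site in zip(samples, sites):
        f = site_factor.get(site, 1.0)
        meta_rows[s] = {"site": site, **{
            v: _SOIL_BASELINES[v] * (f if v not in ("pH",) else 1.0)
               * np.exp(rng.normal(0.0, noise_sd))
            for v in SOIL_VARIABLES}}
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))

    base = _ENZYME_BASELINES[limitation]
    enz_rows = {
        s: {e: base[e] * np.exp(rng.normal(0.0, noise_sd)) for e in ENZYME_COLUMNS}
        for s in samples
    }
    enzymes = EnzymeActivities(pd.DataFrame.from_dict(enz_rows, orient="index"))
    return metadata, enzymes


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    table: AsvTable
    tree: PhylogeneticTree
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    enzymes: EnzymeActivities
    truth: dict = field(default_factory=dict)

    def as_bundle(self) -> Bundle:
        return Bundle(self.table, self.taxonomy, self.tree, self.metadata, self.enzymes)


def _simulate_taxonomy(taxa: Sequence[str], seed: int) -> TaxonomyTable:
    rng = np.random.default_rng(_child_seed(seed, 4))
    phyla = list(SYNTHETIC_PHYLA)
    rows = {}
    for a in taxa:
        p = phyla[int(rng.integers(len(phyla)))]
        rows[a] = {"kingdom": "Bacteria", "phylum": p, "class": "", "order": "",
                   "family": "", "genus": ""}
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))


def make_bundle(spec: RegimeSpec, limitation: str = "balanced",
                noise_sd: float = 0.05) -> SyntheticBundle:
    """Generate all five inputs plus a truth record sufficient to regenerate."""
    tree = simulate_tree(spec.n_taxa, _child_seed(spec.seed, 0))
    optima = simulate_optima_bm(tree, spec.bm_sigma, _child_seed(spec.seed, 1),
                                depth_power=spec.trait_depth_power)
    table, optima = simulate_communities(spec, tree, optima)
    taxonomy = _simulate_taxonomy(table.asv_ids, spec.seed)
    metadata, enzymes = simulate_soil_enzymes(table, limitation, noise_sd, spec.seed)
    truth = {
        "spec": asdict(spec),
        "limitation": limitation,
        "noise_sd": noise_sd,
        "optima": {k: float(v) for k, v in optima.items()},
        "strategy_map": dict(SYNTHETIC_PHYLA),
    }
    return SyntheticBundle(table, tree, taxonomy, metadata, enzymes, truth)


def bundle_from_truth(truth: dict) -> SyntheticBundle:
    """Regenerate a bundle bit-for-bit from its serialized truth record."""
    spec = RegimeSpec(**truth["spec"])
    return make_bundle(spec, truth["limitation"], truth["noise_sd"])


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    from . import io_core

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "asv_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "enzymes": out / "enzymes.tsv",
        "truth": out / "truth.json",
    }
    io_core.write_asv_table(bundle.table, paths["table"])
    io_core.write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    bundle.tree.write(paths["tree"])
    io_core.write_metadata(bundle.metadata, paths["metadata"])
    io_core.write_enzymes(bundle.enzymes, paths["enzymes"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2))
    return paths
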