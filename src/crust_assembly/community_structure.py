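"""Abundant/rare partitioning, life-strategy ratios, alpha/beta diversity.

Taxa are split on their mean relative abundance across all samples: above 1%
of the community they count as abundant, below 0.1% as rare, with the band in
between kept as an explicit intermediate class so the partition is total.
Beta diversity uses Bray-Curtis dissimilarity, ordinated by classical PCoA and
tested with a permutation ANOVA (pseudo-F on distance sums of squares).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import AsvTable, TaxonomyTable

__all__ = [
    "TaxonPartition", "OrdinationResult", "PermanovaResult",
    "DEFAULT_STRATEGY_MAP", "load_strategy_map",
    "to_relative", "partition_taxa", "copiotroph_ratio",
    "shannon", "shannon_index", "bray_curtis_matrix", "pcoa", "permanova",
]

#: phylum -> life strategy defaults (editable stand-in for a literature-derived
#: copiotroph/oligotroph annotation; anything unlisted is unclassified)
DEFAULT_STRATEGY_MAP: dict[str, str] = {
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


def load_strategy_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column TSV (phylum, strategy) overriding the default map entirely."""
    df = pd.read_csv(path, sep=delimiter, header=None, names=["phylum", "strategy"],
                     comment="#")
    bad = set(df["strategy"]) - {"copiotroph", "oligotroph", "unclassified"}
    if bad:
        raise ValueError(f"unknown strategies in map: {sorted(bad)}")
    return dict(zip(df["phylum"].astype(str), df["strategy"]))


def to_relative(table: AsvTable) -> AsvTable:
    """Row-normalize counts to relative abundances (idempotent)."""
    if table.is_relative:
        return AsvTable(table.data.copy(), is_relative=True)
    sums = table.data.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("cannot normalize sample with zero total count")
    return AsvTable(table.data.div(sums, axis=0), is_relative=True)


@dataclass
class TaxonPartition:
    abundant: set[str]
    rare: set[str]
    intermediate: set[str]
    mean_rel_abund: pd.Series
    rare_cut: float = 0.001
    abund_cut: float = 0.01

    def label_of(self, asv_id: str) -> str:
        if asv_id in self.abundant:
            return "abundant"
        if asv_id in self.rare:
            return "rare"
        return "intermediate"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_rel_abund": self.mean_rel_abund,
            "class": [self.label_of(a) for a in self.mean_rel_abund.index],
        })


def partition_taxa(rel: AsvTable, rare_cut: float = 0.001,
                   abund_cut: float = 0.01) -> TaxonPartition:
    """Partition taxa by mean relative abundance across all samples.

    Strict inequalities: mean > abund_cut is abundant, mean < rare_cut is rare,
    everything else (including the cut values themselves) is intermediate.
    """
    if not rel.is_relative:
        raise ValueError("partition_taxa expects a relative-abundance table")
    if not (0 < rare_cut < abund_cut < 1):
        raise ValueError("need 0 < rare_cut < abund_cut < 1")
    mean = rel.data.mean(axis=0)
    abundant = set(mean.index[mean > abund_cut])
    rare = set(mean.index[mean < rare_cut])
    intermediate = set(mean.index) - abundant - rare
    return TaxonPartition(abundant, rare, intermediate, mean, rare_cut, abund_cut)


def copiotroph_ratio(rel: AsvTable, taxonomy: TaxonomyTable,
                     strategy_map: dict[str, str] | None = None) -> pd.Series:
    """Per-sample copiotroph:oligotroph relative-abundance ratio.

    Unclassified phyla are excluded from both sums; a zero oligotroph sum makes
    the ratio undefined (NaN), never infinite.
    """
    smap = DEFAULT_STRATEGY_MAP if strategy_map is None else strategy_map
    strategy = pd.Series(
        [smap.get(taxonomy.phylum_of(a), "unclassified") for a in rel.asv_ids],
        index=rel.asv_ids)
    copio = rel.data.loc[:, strategy == "copiotroph"].sum(axis=1)
    oligo = rel.data.loc[:, strategy == "oligotroph"].sum(axis=1)
    out = copio / oligo.where(oligo > 0)
    return out.rename("copiotroph_oligotroph_ratio")


def shannon(counts_or_rel) -> float:
    """Shannon diversity H = -sum p ln p (natural log) of one community."""
    v = np.asarray(counts_or_rel, dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundance")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero community")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_index(table: AsvTable) -> pd.Series:
    return pd.Series({s: shannon(table.data.loc[s].values) for s in table.sample_ids},
                     name="shannon")


def bray_curtis_matrix(rel: AsvTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    if not rel.is_relative:
        raise ValueError("bray_curtis_matrix expects a relative-abundance table")
    d = squareform(pdist(rel.values, metric="braycurtis"))
    return pd.DataFrame(d, index=rel.sample_ids, columns=rel.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Classical (metric) principal coordinates analysis.

    Eigendecomposition of the Gower-centered matrix -0.5 * J D^2 J; negative
    eigenvalues are dropped from both the axes and the variance-explained
    denominator.  Requested axes beyond the positive spectrum are truncated
    with a warning.
    """
    import warnings

    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"requested {k} axes but only {n_pos} positive eigenvalues")
        k = n_pos
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    prop = eigvals[:k] / eigvals[:n_pos].sum()
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(n))
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels,
                                 columns=[f"PCo{i + 1}" for i in range(k)]),
        eigenvalues=eigvals[:n_pos],
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(dist: pd.DataFrame, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA (pseudo-F over distance sums of squares).

    p uses the add-one permutation estimator (1 + #{F_perm >= F_obs}) /
    (1 + n_perm) over seeded label permutations.
    """
    labels = np.asarray(pd.Series(groups).loc[list(dist.index)]
                        if isinstance(groups, (pd.Series, dict)) else groups)
    D2 = np.asarray(dist, dtype=float) ** 2
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    n, a = len(labels), len(uniq)

    ss_total, ss_within = _permanova_ss(D2, labels)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, ss_w = _permanova_ss(D2, perm)
        f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)
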