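"""Typed containers and file I/O for the five pipeline inputs.

The pipeline works from five flat-text artifacts: an ASV count table
(samples x ASVs), a taxonomy table, a rooted Newick phylogeny with branch
lengths, sample metadata carrying ten soil physicochemical variables, and a
per-sample activity table for seven extracellular enzymes.  Every container
validates its invariants on construction so that downstream stages can assume
clean inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "TaxonomyTable",
    "PhylogeneticTree",
    "SampleMetadata",
    "EnzymeActivities",
    "Bundle",
    "ValidationReport",
    "read_asv_table",
    "read_taxonomy",
    "read_tree",
    "read_metadata",
    "read_enzymes",
    "write_asv_table",
    "write_taxonomy",
    "write_metadata",
    "write_enzymes",
    "validate_bundle",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: soil variables expected in sample metadata, beyond the categorical `site`
SOIL_VARIABLES = (
    "pH", "EC", "SWC", "SOC", "TN", "NH4_N", "NO3_N", "TP", "AP_avail", "AK",
)

#: the seven assayed enzymes: C-acquiring (AG, BG, XS, CB), N-acquiring
#: (NAG, LAP) and P-acquiring (AP)
ENZYME_COLUMNS = ("AG", "BG", "XS", "CB", "NAG", "LAP", "AP")

_REL_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input object violates a container invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what} IDs: {sorted(set(dups))[:5]}")
    return ids


def _coerce_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValidationError(
                f"non-numeric value in {what} at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        if coerced.isna().any():
            row = coerced.isna().idxmax()
            raise ValidationError(f"missing value in {what} at row {row!r}, column {col!r}")
        out[col] = coerced.astype(float)
    return pd.DataFrame(out, index=df.index)


@dataclass
class AsvTable:
    """Samples x ASVs abundance matrix (raw counts or relative abundances)."""

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("AsvTable.data must be a pandas DataFrame")
        self.data.index = pd.Index(_check_unique(self.data.index, "sample"), name="sample_id")
        self.data.columns = pd.Index(_check_unique(self.data.columns, "ASV"), name="asv_id")
        self.data = _coerce_numeric(self.data, "ASV table")
        vals = self.data.values
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"ASV {self.data.columns[c]!r}"
            )
        rowsums = vals.sum(axis=1)
        if (rowsums == 0).any():
            empty = self.data.index[rowsums == 0].tolist()
            raise ValidationError(f"all-zero sample rows: {empty[:5]}")
        if self.is_relative and np.abs(rowsums - 1.0).max() > _REL_TOL:
            worst = self.data.index[np.abs(rowsums - 1.0).argmax()]
            raise ValidationError(f"relative table row {worst!r} does not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    def subset_asvs(self, asv_ids: Sequence[str], renormalize: bool = False) -> "AsvTable":
        """Column subset; optionally re-normalize rows (drops emptied samples)."""
        sub = self.data.loc[:, list(asv_ids)].copy()
        if renormalize:
            sums = sub.sum(axis=1)
            sub = sub.loc[sums > 0].div(sums[sums > 0], axis=0)
            return AsvTable(sub, is_relative=True)
        return AsvTable(sub, is_relative=self.is_relative)


@dataclass
class TaxonomyTable:
    """ASV -> (kingdom..genus) assignments; empty string means unassigned."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = pd.Index(_check_unique(self.data.index, "ASV"), name="asv_id")
        for rank in TAXONOMY_RANKS:
            if rank not in self.data.columns:
                self.data[rank] = ""
        self.data = self.data.loc[:, list(TAXONOMY_RANKS)].fillna("").astype(str)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    def phylum_of(self, asv_id: str) -> str:
        if asv_id not in self.data.index:
            return ""
        return self.data.loc[asv_id, "phylum"]


@dataclass
class PhylogeneticTree:
    """Rooted tree with non-negative branch lengths over ASV tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [t.label for t in self.tree.taxon_namespace if t.label is not None]
        tips = [leaf.taxon.label for leaf in self.tree.leaf_node_iter() if leaf.taxon]
        _check_unique(tips, "tree tip")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge
                continue
            if edge.length is None:
                raise ValidationError("tree edge without branch length")
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        del labels
        self._tips = tips

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def patristic_distances(self, taxa: Sequence[str] | None = None) -> pd.DataFrame:
        """Symmetric matrix of tip-to-tip path lengths (sum of branch lengths)."""
        labels = list(taxa) if taxa is not None else self.tip_labels
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise ValidationError(f"taxa not in tree: {sorted(missing)[:5]}")
        # d(i, j) = depth_i + depth_j - 2 * depth_LCA, accumulated bottom-up:
        # at each internal node, cross-child tip pairs have their LCA there
        all_tips = self.tip_labels
        index_of = {lab: i for i, lab in enumerate(all_tips)}
        n_all = len(all_tips)
        out = np.zeros((n_all, n_all))
        depth: dict[int, float] = {id(self.tree.seed_node): 0.0}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        tipsets: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for node in self.tree.postorder_node_iter():
            if not node.child_nodes():
                i = index_of[node.taxon.label]
                tipsets[id(node)] = (np.array([i]), np.array([depth[id(node)]]))
                continue
            parts = [tipsets.pop(id(c)) for c in node.child_nodes()]
            for a in range(len(parts)):
                ia, da = parts[a]
                for b_ in range(a + 1, len(parts)):
                    ib, db = parts[b_]
                    d = da[:, None] + db[None, :] - 2.0 * depth[id(node)]
                    out[np.ix_(ia, ib)] = d
                    out[np.ix_(ib, ia)] = d.T
            tipsets[id(node)] = (np.concatenate([p[0] for p in parts]),
                                 np.concatenate([p[1] for p in parts]))
        df = pd.DataFrame(out, index=all_tips, columns=all_tips)
        return df.loc[labels, labels]

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        out: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def write(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class SampleMetadata:
    """Per-sample habitat label plus ten soil physicochemical variables.

    Derived stoichiometric ratios C/N = SOC/TN and C/P = SOC/TP are exposed by
    :meth:`with_ratios`; they require strictly positive TN and TP.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = pd.Index(_check_unique(self.data.index, "sample"), name="sample_id")
        if "site" not in self.data.columns:
            raise ValidationError("metadata must carry a 'site' column")
        missing = [v for v in SOIL_VARIABLES if v not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata missing soil variables: {missing}")
        soil = _coerce_numeric(self.data[list(SOIL_VARIABLES)], "metadata")
        if (soil.values < 0).any():
            raise ValidationError("negative soil variable value")
        self.data = pd.concat([self.data[["site"]].astype(str), soil], axis=1)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sites(self) -> pd.Series:
        return self.data["site"]

    def with_ratios(self) -> pd.DataFrame:
        df = self.data.copy()
        if (df["TN"] <= 0).any() or (df["TP"] <= 0).any():
            raise ValidationError("C/N and C/P require TN > 0 and TP > 0")
        df["C_N"] = df["SOC"] / df["TN"]
        df["C_P"] = df["SOC"] / df["TP"]
        return df


@dataclass
class EnzymeActivities:
    """Per-sample activities of the seven assayed enzymes (non-negative)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = pd.Index(_check_unique(self.data.index, "sample"), name="sample_id")
        missing = [e for e in ENZYME_COLUMNS if e not in self.data.columns]
        if missing:
            raise ValidationError(f"enzyme table missing columns: {missing}")
        self.data = _coerce_numeric(self.data[list(ENZYME_COLUMNS)], "enzyme table")
        if (self.data.values < 0).any():
            raise ValidationError("negative enzyme activity")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# readers / writers (TSV by default; configurable delimiter; first column = ID)
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    with open(path) as fh:  # pandas mangles duplicate header IDs; check raw
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"duplicate column IDs in {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return df


def read_asv_table(path: str | Path, orientation: str = "samples",
                   delimiter: str = "\t", is_relative: bool = False) -> AsvTable:
    """Read an abundance table; `orientation` declares what the rows are."""
    if orientation not in ("samples", "asvs"):
        raise ValueError("orientation must be 'samples' or 'asvs'")
    df = _read_table(path, delimiter)
    if orientation == "asvs":
        df = df.T
    return AsvTable(df, is_relative=is_relative)


def read_taxonomy(path: str | Path, delimiter: str = "\t") -> TaxonomyTable:
    return TaxonomyTable(_read_table(path, delimiter))


def read_tree(path: str | Path) -> PhylogeneticTree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"cannot parse Newick file {path}: {exc}") from exc
    return PhylogeneticTree(tree)


def tree_from_newick(newick: str) -> PhylogeneticTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValidationError(f"cannot parse Newick string: {exc}") from exc
    return PhylogeneticTree(tree)


def read_metadata(path: str | Path, delimiter: str = "\t") -> SampleMetadata:
    return SampleMetadata(_read_table(path, delimiter))


def read_enzymes(path: str | Path, delimiter: str = "\t") -> EnzymeActivities:
    return EnzymeActivities(_read_table(path, delimiter))


def write_asv_table(table: AsvTable, path: str | Path, delimiter: str = "\t") -> None:
    table.data.to_csv(path, sep=delimiter)


def write_taxonomy(tax: TaxonomyTable, path: str | Path, delimiter: str = "\t") -> None:
    tax.data.to_csv(path, sep=delimiter)


def write_metadata(meta: SampleMetadata, path: str | Path, delimiter: str = "\t") -> None:
    meta.data.to_csv(path, sep=delimiter)


def write_enzymes(enz: EnzymeActivities, path: str | Path, delimiter: str = "\t") -> None:
    enz.data.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# cross-file consistency
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Cross-file consistency report for a five-input bundle."""

    asvs_missing_from_tree: list[str] = field(default_factory=list)
    asvs_missing_from_taxonomy: list[str] = field(default_factory=list)
    samples_missing_from_metadata: list[str] = field(default_factory=list)
    samples_missing_from_enzymes: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.asvs_missing_from_tree or self.asvs_missing_from_taxonomy
                    or self.samples_missing_from_metadata
                    or self.samples_missing_from_enzymes)

    @property
    def blocks_run(self) -> bool:
        """Missing samples always abort; missing ASVs are configurable."""
        return bool(self.samples_missing_from_metadata or self.samples_missing_from_enzymes)


@dataclass
class Bundle:
    table: AsvTable
    taxonomy: TaxonomyTable
    tree: PhylogeneticTree
    metadata: SampleMetadata
    enzymes: EnzymeActivities


def validate_bundle(table: AsvTable, taxonomy: TaxonomyTable, tree: PhylogeneticTree,
                    metadata: SampleMetadata, enzymes: EnzymeActivities) -> ValidationReport:
    tips = set(tree.tip_labels)
    tax_ids = set(taxonomy.asv_ids)
    meta_ids = set(metadata.sample_ids)
    enz_ids = set(enzymes.sample_ids)
    return ValidationReport(
        asvs_missing_from_tree=[a for a in table.asv_ids if a not in tips],
        asvs_missing_from_taxonomy=[a for a in table.asv_ids if a not in tax_ids],
        samples_missing_from_metadata=[s for s in table.sample_ids if s not in meta_ids],
        samples_missing_from_enzymes=[s for s in table.sample_ids if s not in enz_ids],
    )


def resolve_bundle(bundle: Bundle, missing_asvs: str = "drop") -> Bundle:
    """Harmonize a bundle; `missing_asvs` is 'drop' (warn) or 'error'.

    Samples missing from metadata or enzymes always abort the run.
    """
    import logging

    report = validate_bundle(bundle.table, bundle.taxonomy, bundle.tree,
                             bundle.metadata, bundle.enzymes)
    if report.blocks_run:
        raise ValidationError(
            "samples missing from metadata/enzymes: "
            f"{report.samples_missing_from_metadata + report.samples_missing_from_enzymes}"
        )
    table = bundle.table
    if report.asvs_missing_from_tree:
        if missing_asvs == "error":
            raise ValidationError(
                f"ASVs missing from tree: {report.asvs_missing_from_tree[:5]}")
        logging.getLogger(__name__).warning(
            "dropping %d ASVs absent from the tree", len(report.asvs_missing_from_tree))
        keep = [a for a in table.asv_ids if a not in set(report.asvs_missing_from_tree)]
        table = table.subset_asvs(keep)
    return Bundle(table, bundle.taxonomy, bundle.tree, bundle.metadata, bundle.enzymes)
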