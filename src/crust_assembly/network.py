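"""Co-occurrence networks with a random-matrix-theory correlation cutoff.

Networks are built from Pearson correlations of ln(count + 1) transformed
abundances.  The correlation cutoff is chosen by the RMT transition: as the
threshold rises and inter-module noise edges disappear, the nearest-neighbour
spacing distribution (NNSD) of the thresholded matrix's eigenvalues moves
from the Wigner (GOE) form typical of correlated noise to the Poisson form
e^(-s) typical of modular block structure.  The smallest threshold whose NNSD
is statistically consistent with Poisson is selected.

Topology metrics follow the usual graph-theoretic definitions; modules come
from a deterministic greedy modularity agglomeration (smallest-node-id
tie-break) and "relative modularity" compares the observed Newman Q against
degree-preserving edge-rewired null graphs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .io_core import AsvTable
from .community_structure import TaxonPartition

__all__ = [
    "CorrelationResult", "CoNetwork", "NetworkTopology", "ModuleAssignment",
    "ComplexityScore", "prevalence_filter", "correlation_matrix",
    "rmt_threshold", "build_network", "topology", "modules",
    "sample_complexity", "complexity_vs_ratio",
    "greedy_modularity_partition", "newman_q",
]


def prevalence_filter(table: AsvTable, min_fraction: float) -> AsvTable:
    """Keep ASVs present (count > 0) in at least `min_fraction` of samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    prev = (table.data > 0).mean(axis=0)
    keep = prev.index[prev >= min_fraction]
    if len(keep) == 0:
        raise ValueError("prevalence filter removed every ASV")
    return table.subset_asvs(list(keep))


@dataclass
class CorrelationResult:
    taxa: list[str]
    r: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def correlation_matrix(table: AsvTable, pseudo: float = 1.0) -> CorrelationResult:
    """Pearson correlations of ln(count + pseudo) between ASVs.

    ASVs constant after the log transform cannot be correlated and are
    excluded (recorded in `excluded`).
    """
    if table.shape[0] < 4:
        raise ValueError("need at least 4 samples for correlations")
    logged = np.log(table.values + pseudo)
    sd = logged.std(axis=0)
    keep = sd > 1e-12 * max(1.0, np.abs(logged).max())
    excluded = [a for a, k in zip(table.asv_ids, keep) if not k]
    taxa = [a for a, k in zip(table.asv_ids, keep) if k]
    if len(taxa) < 2:
        raise ValueError("fewer than 2 non-constant ASVs")
    r = np.corrcoef(logged[:, keep], rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationResult(taxa, pd.DataFrame(r, index=taxa, columns=taxa), excluded)


# ---------------------------------------------------------------------------
# RMT threshold selection
# ---------------------------------------------------------------------------

def _nnsd_poisson_pvalue(eigvals: np.ndarray, min_spacings: int = 10,
                         ) -> float | None:
    """Goodness-of-fit p of the unfolded NNSD against Poisson e^(-s).

    Unfolds via a cubic smoothing spline through the cumulative spectral
    density over unique eigenvalues; returns None when the spectrum is too
    degenerate to test.
    """
    lam = np.sort(eigvals)
    uniq, counts = np.unique(np.round(lam, 10), return_counts=True)
    if len(uniq) < max(min_spacings + 1, 5):
        return None
    cum = np.cumsum(counts).astype(float)
    spline = UnivariateSpline(uniq, cum, k=3, s=len(uniq))
    unfolded = spline(uniq)
    s = np.diff(unfolded)
    s = s[s > 0]
    if len(s) < min_spacings or s.mean() <= 0:
        return None
    s = s / s.mean()

    # chi-square GOF: bins of width 0.1 up to s = 3 plus tail, pooled to
    # expected counts >= 5
    edges = np.arange(0.0, 3.0 + 1e-9, 0.1)
    obs_counts, _ = np.histogram(s, bins=np.append(edges, np.inf))
    probs = np.append(-np.diff(np.exp(-edges)), np.exp(-3.0))
    expected = probs * len(s)

    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs_counts, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and pooled_exp:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    if len(pooled_obs) < 2:
        return None
    pooled_exp = np.array(pooled_exp) * (np.sum(pooled_obs) / np.sum(pooled_exp))
    chi2 = float(((np.array(pooled_obs) - pooled_exp) ** 2 / pooled_exp).sum())
    return float(stats.chi2.sf(chi2, df=len(pooled_obs) - 1))


def rmt_threshold(corr: CorrelationResult | pd.DataFrame,
                  t_grid=None, alpha: float = 0.05) -> float:
    """Smallest grid threshold whose thresholded-matrix NNSD looks Poisson.

    Scans t from 0.30 to 0.90 in 0.01 steps by default; at each t entries with
    |r| < t are zeroed (diagonal kept), isolated rows dropped, and the NNSD of
    the remaining spectrum is tested against e^(-s) at level `alpha`.
    """
    R = corr.r if isinstance(corr, CorrelationResult) else corr
    if R.shape[0] < 30:
        raise ValueError("RMT threshold selection needs at least 30 taxa")
    if t_grid is None:
        t_grid = np.round(np.arange(0.30, 0.9001, 0.01), 10)
    M0 = np.asarray(R, dtype=float)
    tested_any = False
    for t in t_grid:
        M = np.where(np.abs(M0) >= t, M0, 0.0)
        np.fill_diagonal(M, 1.0)
        deg = (M != 0).sum(axis=0) - 1
        keep = deg > 0
        if keep.sum() < 12:
            continue
        sub = M[np.ix_(keep, keep)]
        eig = np.linalg.eigvalsh(sub)
        p = _nnsd_poisson_pvalue(eig)
        if p is None:
            continue
        tested_any = True
        if p > alpha:
            return float(t)
    if not tested_any:
        raise ValueError("spectrum too degenerate at every threshold "
                         "(e.g. identity-like correlation matrix)")
    raise ValueError("no threshold in the grid passes the Poisson NNSD test; "
                     "widen the grid")


# ---------------------------------------------------------------------------
# graph construction and metrics
# ---------------------------------------------------------------------------

@dataclass
class CoNetwork:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]


def build_network(corr: CorrelationResult | pd.DataFrame, threshold: float,
                  drop_isolated: bool = True) -> CoNetwork:
    """Signed graph with an edge wherever |r| >= threshold (no self-loops)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    R = corr.r if isinstance(corr, CorrelationResult) else corr
    G = nx.Graph()
    G.add_nodes_from(R.index)
    vals = np.asarray(R, dtype=float)
    ii, jj = np.nonzero(np.triu(np.abs(vals) >= threshold, 1))
    for i, j in zip(ii, jj):
        G.add_edge(R.index[i], R.index[j], r=float(vals[i, j]),
                   sign=1 if vals[i, j] > 0 else -1)
    if drop_isolated:
        G.remove_nodes_from(list(nx.isolates(G)))
    if G.number_of_edges() == 0:
        warnings.warn("empty network at this threshold")
    return CoNetwork(G, float(threshold))


def newman_q(G: nx.Graph, partition) -> float:
    """Newman modularity Q of a node partition (unweighted edges)."""
    m = G.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        comm = set(comm)
        internal = sum(1 for u, v in G.edges(comm) if u in comm and v in comm)
        degree = sum(d for _, d in G.degree(comm))
        q += internal / m - (degree / (2 * m)) ** 2
    return float(q)


def greedy_modularity_partition(G: nx.Graph) -> list[set]:
    """Deterministic CNM-style agglomeration maximizing Newman Q.

    Communities start as singletons and the merge with the largest Q gain is
    applied until no merge improves Q; ties break on the smallest involved
    node id, so repeated runs give identical partitions.
    """
    nodes = sorted(G.nodes, key=str)
    if not nodes:
        return []
    m = G.number_of_edges()
    if m == 0:
        return [{n} for n in nodes]
    comms: dict[int, set] = {i: {n} for i, n in enumerate(nodes)}
    node_comm = {n: i for i, n in enumerate(nodes)}
    # e[i][j]: edges between communities; a[i]: total degree fraction
    e: dict[int, dict[int, float]] = {i: {} for i in comms}
    a = {i: 0.0 for i in comms}
    for u, v in G.edges:
        cu, cv = node_comm[u], node_comm[v]
        e[cu][cv] = e[cu].get(cv, 0) + 1
        if cu != cv:
            e[cv][cu] = e[cv].get(cu, 0) + 1
    for n in nodes:
        a[node_comm[n]] += G.degree(n) / (2 * m)

    def key_of(i: int):
        return str(min(comms[i], key=str))

    def q_now() -> float:
        return sum(e[i].get(i, 0) / m - a[i] ** 2 for i in comms)

    best_q = q_now()
    best_partition = [set(c) for c in comms.values()]
    while len(comms) > 1:
        best = None
        for i in comms:
            for j, eij in e[i].items():
                if j not in comms or j <= i:
                    continue  # each unordered pair once; skip internal e[i][i]
                dq = eij / m - 2 * a[i] * a[j]
                keys = sorted((key_of(i), key_of(j)))
                if best is None or dq > best[0] + 1e-15 or (
                        abs(dq - best[0]) <= 1e-15 and keys < best[3]):
                    best = (dq, i, j, keys)
        if best is None:
            break  # disconnected remainder: no linked pair left to merge
        _, i, j, _ = best
        # merge j into i
        comms[i] |= comms.pop(j)
        for k, v in e[j].items():
            if k == j:
                e[i][i] = e[i].get(i, 0) + v
            elif k == i:
                e[i][i] = e[i].get(i, 0) + v
            else:
                e[i][k] = e[i].get(k, 0) + v
                e[k][i] = e[k].get(i, 0) + v
                e[k].pop(j, None)
        e.pop(j)
        e[i].pop(j, None)
        for k in list(e):
            e[k].pop(j, None)
        a[i] += a.pop(j)
        q = q_now()
        if q > best_q + 1e-15:
            best_q = q
            best_partition = [set(c) for c in comms.values()]
    return sorted(best_partition, key=lambda c: str(min(c, key=str)))


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    avg_degree: float
    diameter: float
    avg_path_length: float
    avg_clustering: float
    modularity: float
    relative_modularity: float

    def as_dict(self) -> dict:
        return dict(vars(self))


def topology(net: CoNetwork, n_rewire_null: int = 100, seed: int = 0) -> NetworkTopology:
    """Standard topology metrics; path metrics use the largest component.

    Relative modularity is (Q - mean Q_null) / mean Q_null over
    degree-preserving edge-rewired null graphs.
    """
    G = net.graph
    n, m = G.number_of_nodes(), G.number_of_edges()
    if n < 2 or m < 1:
        nan = float("nan")
        return NetworkTopology(n, m, nan, nan, nan, nan, nan, nan)
    avg_degree = 2 * m / n
    clustering = nx.average_clustering(G)  # degree-<2 nodes count 0
    giant = G.subgraph(max(nx.connected_components(G), key=len))
    diam = nx.diameter(giant)
    apl = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
    q = newman_q(G, greedy_modularity_partition(G))

    rng = np.random.default_rng(seed)
    q_null = []
    for _ in range(n_rewire_null):
        H = G.copy()
        try:
            nx.double_edge_swap(H, nswap=4 * m, max_tries=40 * m + 100,
                                seed=int(rng.integers(2 ** 31)))
        except nx.NetworkXException:
            pass  # too few swappable edges; use as-is
        q_null.append(newman_q(H, greedy_modularity_partition(H)))
    mean_null = float(np.mean(q_null)) if q_null else float("nan")
    rel_mod = (q - mean_null) / mean_null if mean_null and np.isfinite(mean_null) else float("nan")
    return NetworkTopology(n, m, float(avg_degree), float(diam), float(apl),
                           float(clustering), float(q), float(rel_mod))


@dataclass
class ModuleAssignment:
    membership: dict[str, int]            # node -> 1-based module rank by size
    sizes: dict[int, int]
    fractions: pd.DataFrame | None        # per-module abundant/rare/intermediate
    large: dict[int, bool]
    min_large: int = 5


def modules(net: CoNetwork, partition: TaxonPartition | None = None,
            min_large: int = 5) -> ModuleAssignment:
    """Deterministic modules ranked by size (module 1 = largest)."""
    if net.graph.number_of_edges() < 1:
        raise ValueError("module detection needs at least one edge")
    comms = greedy_modularity_partition(net.graph)
    comms = sorted(comms, key=lambda c: (-len(c), str(min(c, key=str))))
    membership = {n: i + 1 for i, c in enumerate(comms) for n in c}
    sizes = {i + 1: len(c) for i, c in enumerate(comms)}
    large = {mid: size >= min_large for mid, size in sizes.items()}
    fractions = None
    if partition is not None:
        rows = {}
        for mid, comm in enumerate(comms, start=1):
            labels = pd.Series([partition.label_of(n) for n in comm])
            frac = labels.value_counts(normalize=True)
            rows[mid] = {c: float(frac.get(c, 0.0))
                         for c in ("abundant", "intermediate", "rare")}
        fractions = pd.DataFrame.from_dict(rows, orient="index")
    return ModuleAssignment(membership, sizes, fractions, large, min_large)


# ---------------------------------------------------------------------------
# per-sample complexity
# ---------------------------------------------------------------------------

DEFAULT_COMPLEXITY_PROPERTIES = ("avg_degree", "avg_clustering", "n_edges")


@dataclass
class ComplexityScore:
    scores: pd.Series                      # composite z-score per sample
    detail: pd.DataFrame


def sample_complexity(net: CoNetwork, table: AsvTable,
                      properties=DEFAULT_COMPLEXITY_PROPERTIES) -> ComplexityScore:
    """Composite z-score of subnetwork properties per sample.

    Each sample induces the subgraph on its present (count > 0) taxa; the
    chosen properties are z-scored across samples (population SD) and
    averaged.  Samples with an empty induced subgraph, and properties constant
    across samples, yield missing values.
    """
    rows = {}
    node_set = set(net.graph.nodes)
    for s in table.sample_ids:
        present = set(table.data.columns[table.data.loc[s] > 0]) & node_set
        H = net.graph.subgraph(present)
        if H.number_of_nodes() == 0:
            rows[s] = {p: np.nan for p in properties}
            continue
        vals = {
            "n_nodes": H.number_of_nodes(),
            "n_edges": H.number_of_edges(),
            "avg_degree": 2 * H.number_of_edges() / H.number_of_nodes(),
            "avg_clustering": nx.average_clustering(H) if H.number_of_nodes() else 0.0,
        }
        rows[s] = {p: vals[p] for p in properties}
    detail = pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]

    zcols = {}
    for p in properties:
        col = detail[p]
        ok = col.notna()
        sd = col[ok].std(ddof=0)
        if not ok.any() or sd <= 1e-12 * max(1.0, col[ok].abs().max()):
            warnings.warn(f"complexity property {p!r} constant; dropped")
            continue
        z = pd.Series(np.nan, index=detail.index)
        z[ok] = (col[ok] - col[ok].mean()) / sd
        zcols[p] = z
    if not zcols:
        composite = pd.Series(np.nan, index=detail.index)
    else:
        composite = pd.DataFrame(zcols).mean(axis=1)
        composite -= composite.mean()  # recenter after averaging/missing
    return ComplexityScore(composite.rename("complexity"), detail)


def complexity_vs_ratio(score: ComplexityScore, ratios: pd.DataFrame,
                        which: str = "cn") -> dict:
    """OLS of the composite on one enzyme log-ratio (slope, Pearson r, p)."""
    if which not in ratios.columns:
        raise ValueError(f"unknown ratio {which!r}")
    paired = pd.concat([score.scores, ratios[which]], axis=1).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    x = paired[which].values
    y = paired.iloc[:, 0].values
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue), "p": float(fit.pvalue), "n": int(len(paired))}
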