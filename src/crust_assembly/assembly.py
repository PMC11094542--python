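"""Null-model partitioning of community assembly processes.

For every sample pair the pipeline computes

* betaMNTD, the abundance-weighted mean distance from each taxon to its
  nearest phylogenetic neighbour in the partner community (conspecifics count
  as distance zero);
* betaNTI, the z-score of observed betaMNTD against a null built by shuffling
  taxon identities across the tips of the patristic distance matrix;
* RC_bray, the position of the observed Bray-Curtis dissimilarity within a
  probabilistic reassembly null that preserves each sample's richness and
  total abundance while drawing membership by occupancy and abundance by
  metacommunity relative abundance, rescaled to [-1, 1].

The two metrics jointly classify each pair into one of five processes:
betaNTI > +2 heterogeneous selection, betaNTI < -2 homogeneous selection,
and within the +/-2 band RC_bray > +0.95 dispersal limitation,
RC_bray < -0.95 homogenizing dispersal, otherwise undominated.  Pairs whose
null distribution is degenerate (zero spread) are reported as undefined
rather than forced into a class.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_core import AsvTable, PhylogeneticTree, SampleMetadata

__all__ = [
    "beta_mntd", "beta_mntd_matrix", "beta_nti", "beta_nti_matrix",
    "raup_crick_bray", "raup_crick_matrix", "classify_process",
    "pairwise_assembly", "assembly_summary", "mantel", "env_distance",
    "MantelResult", "PROCESSES",
]

PROCESSES = (
    "heterogeneous_selection", "homogeneous_selection",
    "dispersal_limitation", "homogenizing_dispersal", "undominated",
)


def _as_dist(dist) -> pd.DataFrame:
    if isinstance(dist, PhylogeneticTree):
        return dist.patristic_distances()
    return dist


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _bmntd_idx(D: np.ndarray, ia: np.ndarray, ib: np.ndarray,
               fa: np.ndarray, fb: np.ndarray) -> float:
    sub = D[np.ix_(ia, ib)]
    return 0.5 * (fa @ sub.min(axis=1) + fb @ sub.min(axis=0))


def beta_mntd(a, b, dist: pd.DataFrame, weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance.

    `a` and `b` are abundance vectors indexed like `dist`; taxa shared by both
    communities contribute zero (their nearest neighbour is themselves).
    The weighted form weights each taxon by its within-sample relative
    abundance; the incidence form averages over present taxa.
    """
    a = pd.Series(a, index=dist.index) if not isinstance(a, pd.Series) else a.loc[dist.index]
    b = pd.Series(b, index=dist.index) if not isinstance(b, pd.Series) else b.loc[dist.index]
    ia = np.flatnonzero(a.values > 0)
    ib = np.flatnonzero(b.values > 0)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty community in beta_mntd")
    if weighted:
        fa = a.values[ia] / a.values[ia].sum()
        fb = b.values[ib] / b.values[ib].sum()
    else:
        fa = np.full(len(ia), 1.0 / len(ia))
        fb = np.full(len(ib), 1.0 / len(ib))
    return float(_bmntd_idx(dist.values, ia, ib, fa, fb))


def beta_mntd_matrix(table: AsvTable, dist, weighted: bool = True) -> pd.DataFrame:
    """All pairwise betaMNTD values for the samples of `table`."""
    D = _as_dist(dist).loc[table.asv_ids, table.asv_ids]
    samples = table.sample_ids
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for sa, sb in combinations(samples, 2):
        v = beta_mntd(table.data.loc[sa], table.data.loc[sb], D, weighted)
        out.loc[sa, sb] = out.loc[sb, sa] = v
    return out


def beta_nti_matrix(table: AsvTable, dist, n_null: int = 999, seed: int = 0,
                    weighted: bool = True, null_scope: str = "pool",
                    ) -> pd.DataFrame:
    """Pairwise betaNTI; NaN marks pairs with a degenerate null (sd = 0).

    The null shuffles taxon identities across the tips of the distance matrix
    (`null_scope="pool"`: all taxa of the table, the regional pool;
    `"union"`: only the taxa present in each pair).  One shuffle per
    replicate is shared by all pairs, as in standard practice.
    """
    if null_scope not in ("pool", "union"):
        raise ValueError("null_scope must be 'pool' or 'union'")
    D = _as_dist(dist).loc[table.asv_ids, table.asv_ids].values
    X = table.values.astype(float)
    n_s, n_t = X.shape
    rng = np.random.default_rng(seed)

    pres = [np.flatnonzero(X[s] > 0) for s in range(n_s)]
    freqs = []
    for s in range(n_s):
        if weighted:
            f = X[s][pres[s]] / X[s][pres[s]].sum()
        else:
            f = np.full(len(pres[s]), 1.0 / len(pres[s]))
        freqs.append(f)

    pairs = list(combinations(range(n_s), 2))
    obs = np.array([_bmntd_idx(D, pres[a], pres[b], freqs[a], freqs[b])
                    for a, b in pairs])

    nsum = np.zeros(len(pairs))
    nsumsq = np.zeros(len(pairs))
    for _ in range(n_null):
        if null_scope == "pool":
            perm = rng.permutation(n_t)
            Dp = D[np.ix_(perm, perm)]
            null = np.array([_bmntd_idx(Dp, pres[a], pres[b], freqs[a], freqs[b])
                             for a, b in pairs])
        else:
            null = np.empty(len(pairs))
            for k, (a, b) in enumerate(pairs):
                union = np.union1d(pres[a], pres[b])
                local = rng.permutation(union)
                remap = dict(zip(union, local))
                ia = np.array([remap[i] for i in pres[a]])
                ib = np.array([remap[i] for i in pres[b]])
                null[k] = _bmntd_idx(D, ia, ib, freqs[a], freqs[b])
        nsum += null
        nsumsq += null ** 2

    mean = nsum / n_null
    var = np.maximum(nsumsq / n_null - mean ** 2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)

    samples = table.sample_ids
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for (a, b), v in zip(pairs, z):
        out.iloc[a, b] = out.iloc[b, a] = v
    np.fill_diagonal(out.values, 0.0)
    return out


def beta_nti(a, b, dist, n_null: int = 999, seed: int = 0,
             weighted: bool = True, null_scope: str = "pool") -> float:
    """betaNTI for a single pair of abundance vectors (NaN if degenerate)."""
    D = _as_dist(dist)
    df = pd.DataFrame([pd.Series(a, index=D.index) if not isinstance(a, pd.Series) else a,
                       pd.Series(b, index=D.index) if not isinstance(b, pd.Series) else b])
    df.index = ["A", "B"]
    if (df.sum(axis=1) == 0).any():
        raise ValueError("empty community in beta_nti")
    table = AsvTable(df)
    m = beta_nti_matrix(table, D.loc[table.asv_ids, table.asv_ids],
                        n_null=n_null, seed=seed, weighted=weighted,
                        null_scope=null_scope)
    return float(m.loc["A", "B"])


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)
# ---------------------------------------------------------------------------

def _bray(u: np.ndarray, v: np.ndarray) -> float:
    tot = u.sum() + v.sum()
    return 1.0 - 2.0 * np.minimum(u, v).sum() / tot


def _null_communities(rng, n_null: int, richness: int, total: int,
                      occupancy: np.ndarray, meta: np.ndarray) -> np.ndarray:
    """n_null count vectors preserving richness and total abundance.

    Membership: weighted draw without replacement by occupancy (Gumbel top-k);
    abundance: one read per member, remainder multinomial on metacommunity
    relative abundances restricted to the drawn members.
    """
    n_t = len(occupancy)
    with np.errstate(divide="ignore"):
        logw = np.where(occupancy > 0, np.log(occupancy), -np.inf)
    keys = logw[None, :] + rng.gumbel(size=(n_null, n_t))
    members = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_null, n_t))
    np.put_along_axis(out, members, 1.0, axis=1)
    extra = total - richness
    if extra > 0:
        w = meta[members]
        w = w / w.sum(axis=1, keepdims=True)
        for r in range(n_null):
            out[r, members[r]] += rng.multinomial(extra, w[r])
    return out


def raup_crick_matrix(table: AsvTable, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Pairwise Raup-Crick (Bray-Curtis) in [-1, 1] over the table's pool.

    RC = 2 * ((#{null < obs} + 0.5 * #{null = obs}) / n_null - 0.5); positive
    values mean the pair is more dissimilar than the reassembly null expects.
    """
    X = table.values.astype(float)
    n_s, n_t = X.shape
    if n_s < 2:
        raise ValueError("pool needs at least 2 samples")
    occupancy = (X > 0).mean(axis=0)
    rel = X / X.sum(axis=1, keepdims=True)
    meta = rel.mean(axis=0)
    meta = meta / meta.sum()
    occ = np.where(occupancy > 0, occupancy, 0.0)

    richness = (X > 0).sum(axis=1)
    totals = X.sum(axis=1).astype(int)
    rng = np.random.default_rng(seed)

    samples = table.sample_ids
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for a, b in combinations(range(n_s), 2):
        null_a = _null_communities(rng, n_null, int(richness[a]), int(totals[a]), occ, meta)
        null_b = _null_communities(rng, n_null, int(richness[b]), int(totals[b]), occ, meta)
        tot = null_a.sum(axis=1) + null_b.sum(axis=1)
        null_bc = 1.0 - 2.0 * np.minimum(null_a, null_b).sum(axis=1) / tot
        obs = _bray(X[a], X[b])
        less = (null_bc < obs - 1e-12).sum()
        ties = (np.abs(null_bc - obs) <= 1e-12).sum()
        rc = 2.0 * ((less + 0.5 * ties) / n_null - 0.5)
        out.iloc[a, b] = out.iloc[b, a] = rc
    return out


def raup_crick_bray(a_id: str, b_id: str, pool: AsvTable,
                    n_null: int = 999, seed: int = 0) -> float:
    """RC_bray for one sample pair drawn from `pool`."""
    m = raup_crick_matrix(pool, n_null=n_null, seed=seed)
    return float(m.loc[a_id, b_id])


# ---------------------------------------------------------------------------
# process classification and summaries
# ---------------------------------------------------------------------------

def classify_process(bnti: float, rc: float, bnti_cut: float = 2.0,
                     rc_cut: float = 0.95) -> str:
    """Five-way assembly call; boundary values fall in the inner bands."""
    if not (np.isfinite(bnti) and np.isfinite(rc)):
        return "undefined"
    if bnti > bnti_cut:
        return "heterogeneous_selection"
    if bnti < -bnti_cut:
        return "homogeneous_selection"
    if rc > rc_cut:
        return "dispersal_limitation"
    if rc < -rc_cut:
        return "homogenizing_dispersal"
    return "undominated"


def pairwise_assembly(table: AsvTable, dist, n_null: int = 999, seed: int = 0,
                      weighted: bool = True, null_scope: str = "pool",
                      bnti_cut: float = 2.0, rc_cut: float = 0.95) -> pd.DataFrame:
    """Long-form table of (sample_a, sample_b, bnti, rc_bray, process)."""
    bnti = beta_nti_matrix(table, dist, n_null=n_null, seed=seed,
                           weighted=weighted, null_scope=null_scope)
    rc = raup_crick_matrix(table, n_null=n_null, seed=seed + 1)
    rows = []
    for sa, sb in combinations(table.sample_ids, 2):
        b, r = bnti.loc[sa, sb], rc.loc[sa, sb]
        rows.append({"sample_a": sa, "sample_b": sb, "bnti": b, "rc_bray": r,
                     "process": classify_process(b, r, bnti_cut, rc_cut)})
    return pd.DataFrame(rows)


def assembly_summary(pairs: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Process fractions over defined within-group pairs.

    `groups` maps sample -> group; pairs spanning two groups are skipped.
    Undefined pairs are excluded from the fractions and counted separately.
    """
    if groups is None:
        gmap = {s: "all" for s in set(pairs["sample_a"]) | set(pairs["sample_b"])}
    else:
        gmap = dict(groups)
    rows = {}
    for g in sorted(set(gmap.values())):
        sel = pairs[[gmap.get(a) == g and gmap.get(b) == g
                     for a, b in zip(pairs["sample_a"], pairs["sample_b"])]]
        defined = sel[sel["process"] != "undefined"]
        if len(sel) and not len(defined):
            raise ValueError(f"all pairs undefined in group {g!r}")
        if not len(sel):
            continue
        frac = defined["process"].value_counts(normalize=True)
        rows[g] = {p: float(frac.get(p, 0.0)) for p in PROCESSES}
        rows[g]["n_pairs"] = int(len(defined))
        rows[g]["n_undefined"] = int(len(sel) - len(defined))
    if not rows:
        raise ValueError("no within-group pairs")
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    variable: str = ""
    method: str = "pearson"


def env_distance(metadata: SampleMetadata, variable: str,
                 samples=None) -> pd.DataFrame:
    """Euclidean (absolute-difference) distance matrix of one soil variable."""
    df = metadata.with_ratios()
    if variable not in df.columns:
        raise ValueError(f"unknown variable {variable!r}")
    v = df[variable].astype(float)
    if samples is not None:
        v = v.loc[list(samples)]
    d = np.abs(v.values[:, None] - v.values[None, :])
    return pd.DataFrame(d, index=v.index, columns=v.index)


def mantel(m1: pd.DataFrame, m2: pd.DataFrame, n_perm: int = 999, seed: int = 0,
           method: str = "pearson", variable: str = "") -> MantelResult:
    """Mantel correlation between two aligned distance matrices.

    p is one-sided (greater), estimated by jointly permuting rows/columns of
    the second matrix with the add-one estimator.
    """
    if list(m1.index) != list(m2.index):
        m2 = m2.loc[m1.index, m1.index]
    A = np.asarray(m1, dtype=float)
    B = np.asarray(m2, dtype=float)
    n = A.shape[0]
    iu = np.triu_indices(n, 1)

    def flat(M):
        v = M[iu]
        if method == "spearman":
            v = pd.Series(v).rank().values
        return v

    va = flat(A)
    if va.std() == 0:
        raise ValueError("constant first matrix")
    vb = flat(B)
    if vb.std() == 0:
        raise ValueError("constant second matrix")
    r_obs = float(np.corrcoef(va, vb)[0, 1])

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(va, flat(B[np.ix_(perm, perm)]))[0, 1]
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm, variable, method)
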