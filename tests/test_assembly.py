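"""Null-model assembly metrics against brute-force and analytical oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crust_assembly import assembly as asm
from crust_assembly import synthetic_data as sd
from crust_assembly.io_core import AsvTable, tree_from_newick


def brute_force_bmntd(a, b, dist, weighted=True):
    """Independent double-loop reference for the nearest-taxon statistic."""
    pa = [t for t in dist.index if a[t] > 0]
    pb = [t for t in dist.index if b[t] > 0]
    fa = {t: (a[t] / sum(a[t2] for t2 in pa)) if weighted else 1 / len(pa) for t in pa}
    fb = {t: (b[t] / sum(b[t2] for t2 in pb)) if weighted else 1 / len(pb) for t in pb}
    total = 0.0
    for t in pa:
        total += fa[t] * min(dist.loc[t, u] for u in pb)
    for u in pb:
        total += fb[u] * min(dist.loc[t, u] for t in pa)
    return 0.5 * total


class TestBetaMntd:
    def test_identical_communities_zero(self, cherry_tree):
        D = cherry_tree.patristic_distances()
        v = pd.Series({"a": 2.0, "b": 1.0, "c": 0.0})
        assert asm.beta_mntd(v, v, D) == 0.0

    def test_cherry_single_taxa(self, cherry_tree):
        D = cherry_tree.patristic_distances()
        a = pd.Series({"a": 1.0, "b": 0.0, "c": 0.0})
        b = pd.Series({"a": 0.0, "b": 5.0, "c": 0.0})
        assert asm.beta_mntd(a, b, D) == pytest.approx(2.0)

    def test_star_tree_disjoint_abundance_free(self):
        star = tree_from_newick("(a:1.5,b:1.5,c:1.5,d:1.5);")
        D = star.patristic_distances()
        a = pd.Series({"a": 0.9, "b": 0.1, "c": 0, "d": 0})
        b = pd.Series({"a": 0, "b": 0, "c": 5, "d": 1})
        assert asm.beta_mntd(a, b, D) == pytest.approx(3.0)

    def test_symmetry_and_rescaling_invariance(self, six_tip_trees):
        D = six_tip_trees[0].patristic_distances()
        rng = np.random.default_rng(0)
        a = pd.Series(rng.integers(0, 5, 6), index=D.index, dtype=float)
        b = pd.Series(rng.integers(0, 5, 6), index=D.index, dtype=float)
        a["a"] += 1
        b["f"] += 1
        assert asm.beta_mntd(a, b, D) == pytest.approx(asm.beta_mntd(b, a, D))
        assert asm.beta_mntd(a * 7, b, D) == pytest.approx(asm.beta_mntd(a, b, D))

    def test_brute_force_equivalence_all_pairs(self, six_tip_trees):
        """Every nonempty community pair on three 6-tip trees matches the
        double-loop oracle to 1e-12 (a subset runs again in acceptance)."""
        for tree in six_tip_trees[:1]:
            D = tree.patristic_distances()
            tips = list(D.index)
            subsets = [s for r in range(1, 4) for s in itertools.combinations(tips, r)]
            for sa in subsets[::3]:
                for sb in subsets[::4]:
                    a = pd.Series({t: 1.0 + (t in sa[:1]) if t in sa else 0.0 for t in tips})
                    b = pd.Series({t: 2.0 if t in sb else 0.0 for t in tips})
                    assert asm.beta_mntd(a, b, D) == pytest.approx(
                        brute_force_bmntd(a, b, D), abs=1e-12)

    def test_empty_community_rejected(self, cherry_tree):
        D = cherry_tree.patristic_distances()
        z = pd.Series({"a": 0.0, "b": 0.0, "c": 0.0})
        with pytest.raises(ValueError):
            asm.beta_mntd(z, z + 1, D)


class TestBetaNti:
    def test_star_tree_null_degenerate(self):
        star = tree_from_newick("(a:1,b:1,c:1,d:1);")
        D = star.patristic_distances()
        a = pd.Series({"a": 1.0, "b": 1.0, "c": 0, "d": 0})
        b = pd.Series({"a": 0, "b": 0, "c": 1.0, "d": 1.0})
        z = asm.beta_nti(a, b, D, n_null=99, seed=0)
        assert np.isnan(z)  # shuffle-invariant statistic: undefined, not 0

    def test_neutral_null_consistency_small(self):
        """Neutral sampling gives centered betaNTI (bigger run in acceptance)."""
        spec = sd.default_regime_spec("neutral", n_samples=8, depth=2000,
                                      n_taxa=100, seed=5)
        tree = sd.simulate_tree(100, sd._child_seed(5, 0))
        table, _ = sd.simulate_communities(spec, tree)
        z = asm.beta_nti_matrix(table, tree.patristic_distances(table.asv_ids),
                                n_null=99, seed=5)
        vals = z.values[np.triu_indices(8, 1)]
        assert np.nanmean(np.abs(vals)) < 2.0
        assert np.mean(np.abs(vals[~np.isnan(vals)]) <= 2) >= 0.8

    def test_deterministic_given_seed(self):
        spec = sd.default_regime_spec("neutral", n_samples=4, depth=500,
                                      n_taxa=30, seed=2)
        tree = sd.simulate_tree(30, seed=2)
        table, _ = sd.simulate_communities(spec, tree)
        D = tree.patristic_distances(table.asv_ids)
        z1 = asm.beta_nti_matrix(table, D, n_null=49, seed=9)
        z2 = asm.beta_nti_matrix(table, D, n_null=49, seed=9)
        pd.testing.assert_frame_equal(z1, z2)


class TestRaupCrick:
    def _table(self, rows, taxa=None):
        taxa = taxa or [f"t{i}" for i in range(len(rows[0]))]
        return AsvTable(pd.DataFrame(np.asarray(rows, float),
                                     index=[f"s{i}" for i in range(len(rows))],
                                     columns=taxa))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        table = self._table(rng.integers(0, 20, size=(5, 12)) + (rng.random((5, 12)) < 0.3))
        rc = asm.raup_crick_matrix(table, n_null=49, seed=1)
        vals = rc.values[np.triu_indices(5, 1)]
        assert ((vals >= -1) & (vals <= 1)).all()

    def test_identical_ubiquitous_communities_rc_minus_one(self):
        """Observed dissimilarity of 0 sits below every stochastic null draw."""
        for seed in range(5):
            table = self._table([[50, 30, 20, 10, 5, 1]] * 2 + [[30, 30, 20, 10, 5, 5]])
            rc = asm.raup_crick_matrix(table, n_null=199, seed=seed)
            assert rc.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_disjoint_rare_taxa_rc_positive(self):
        """Samples occupying disjoint pool-rare taxa are more dissimilar than
        the occupancy-weighted null expects."""
        rng = np.random.default_rng(3)
        base = rng.integers(5, 15, size=(6, 20))
        rows = np.hstack([base, np.zeros((6, 8))])
        rows[0, 20:24] = [40, 30, 20, 10]   # s0: rare block one
        rows[1, 24:28] = [40, 30, 20, 10]   # s1: rare block two
        rows[0, :20] = 0
        rows[1, :20] = 0
        table = self._table(rows)
        vals = [asm.raup_crick_matrix(table, n_null=199, seed=s).loc["s0", "s1"]
                for s in range(5)]
        assert np.mean(vals) > 0.5

    def test_pool_too_small_rejected(self):
        table = self._table([[1, 2, 3]])
        with pytest.raises(ValueError):
            asm.raup_crick_matrix(table)


class TestClassifyProcess:
    @pytest.mark.parametrize("bnti,rc,expect", [
        (2.5, 0.1, "heterogeneous_selection"),
        (-2.5, 0.99, "homogeneous_selection"),
        (0.0, 0.97, "dispersal_limitation"),
        (0.0, -0.97, "homogenizing_dispersal"),
        (-1.0, 0.0, "undominated"),
        (2.0, 0.97, "dispersal_limitation"),    # boundary: not selection
        (-2.0, -0.97, "homogenizing_dispersal"),
        (0.0, 0.95, "undominated"),             # boundary: not dispersal
        (0.0, -0.95, "undominated"),
        (np.nan, 0.5, "undefined"),
        (1.0, np.nan, "undefined"),
    ])
    def test_truth_table(self, bnti, rc, expect):
        assert asm.classify_process(bnti, rc) == expect

    @given(st.floats(-6, 6, allow_nan=False), st.floats(-1, 1, allow_nan=False))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_exhaustive_and_exclusive(self, bnti, rc):
        assert asm.classify_process(bnti, rc) in asm.PROCESSES


class TestSummaryAndMantel:
    def test_fractions_sum_to_one(self):
        pairs = pd.DataFrame({
            "sample_a": ["s1", "s1", "s2"], "sample_b": ["s2", "s3", "s3"],
            "bnti": [0, 0, 3], "rc_bray": [0.99, 0.99, 0.5],
            "process": ["dispersal_limitation", "dispersal_limitation",
                        "heterogeneous_selection"]})
        out = asm.assembly_summary(pairs)
        assert out.loc["all", list(asm.PROCESSES)].sum() == pytest.approx(1.0)
        assert out.loc["all", "dispersal_limitation"] == pytest.approx(2 / 3)

    def test_undefined_pairs_counted_separately(self):
        pairs = pd.DataFrame({
            "sample_a": ["s1", "s1"], "sample_b": ["s2", "s3"],
            "bnti": [0, np.nan], "rc_bray": [0.99, 0.5],
            "process": ["dispersal_limitation", "undefined"]})
        out = asm.assembly_summary(pairs)
        assert out.loc["all", "n_undefined"] == 1
        assert out.loc["all", "dispersal_limitation"] == pytest.approx(1.0)

    def test_all_undefined_rejected(self):
        pairs = pd.DataFrame({
            "sample_a": ["s1"], "sample_b": ["s2"],
            "bnti": [np.nan], "rc_bray": [0.5], "process": ["undefined"]})
        with pytest.raises(ValueError):
            asm.assembly_summary(pairs)

    def test_mantel_self_correlation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        D = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=2))
        res = asm.mantel(D, D * 3.0, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_mantel_spearman_monotone_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 2))
        D = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=2))
        E = pd.DataFrame(rng.random((7, 7)))
        E = (E + E.T) / 2
        np.fill_diagonal(E.values, 0)
        r1 = asm.mantel(D, E, n_perm=49, seed=3, method="spearman").r
        r2 = asm.mantel(D, E ** 3, n_perm=49, seed=3, method="spearman").r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_mantel_constant_matrix_rejected(self):
        D = pd.DataFrame(np.zeros((4, 4)))
        E = pd.DataFrame(1.0 - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            asm.mantel(D, E, n_perm=9)

    def test_mantel_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        p1 = rng.normal(size=(9, 2))
        p2 = p1 + rng.normal(0, 0.5, size=(9, 2))
        D1 = pd.DataFrame(np.linalg.norm(p1[:, None] - p1[None, :], axis=2))
        D2 = pd.DataFrame(np.linalg.norm(p2[:, None] - p2[None, :], axis=2))
        ours = asm.mantel(D1, D2, n_perm=9, seed=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(D1.values), skbio.DistanceMatrix(D2.values),
            permutations=9)
        assert ours.r == pytest.approx(r_ref, abs=1e-9)

    def test_env_distance_absolute_differences(self, metadata_two_sites):
        d = asm.env_distance(metadata_two_sites, "SOC")
        soc = metadata_two_sites.data["SOC"]
        assert d.loc["s1", "s3"] == pytest.approx(abs(soc["s1"] - soc["s3"]))
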