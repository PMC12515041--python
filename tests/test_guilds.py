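import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import guildcraft as gc


def naive_ward_cophenetic(d):
    """Independent Ward.D2 oracle via the Lance-Williams update, returning
    the cophenetic (merge-height) matrix between leaves."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(
            (((i, j), dist[frozenset((i, j))])
             for i in clusters for j in clusters if i < j),
            key=lambda kv: kv[1],
        )
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) + clusters.pop(b)
        for k in list(clusters):
            nk = len(clusters[k])
            dak = dist.pop(frozenset((a, k)))
            dbk = dist.pop(frozenset((b, k)))
            dist[frozenset((next_id, k))] = np.sqrt(
                ((na + nk) * dak**2 + (nb + nk) * dbk**2 - nk * h**2)
                / (na + nb + nk)
            )
        dist.pop(frozenset((a, b)))
        clusters[next_id] = merged
        next_id += 1
    return coph


def frame(d, ids=None):
    ids = ids or [f"f{i}" for i in range(d.shape[0])]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestWardTree:
    def test_planted_pairs_merge_first(self):
        d = np.full((4, 4), 1.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0)
        tree = gc.ward_tree(frame(d))
        first_two = {frozenset(tree.linkage[i, :2].astype(int)) for i in range(2)}
        assert first_two == {frozenset((0, 1)), frozenset((2, 3))}

    def test_identical_rows_merge_at_zero(self):
        d = np.array([[0, 0.0, 1], [0.0, 0, 1], [1, 1, 0]], dtype=float)
        tree = gc.ward_tree(frame(d))
        assert tree.linkage[0, 2] == 0.0

    def test_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.2, 1.8, (10, 10))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        tree = gc.ward_tree(frame(d))
        coph = hierarchy.cophenet(tree.linkage)
        expected = naive_ward_cophenetic(d)[np.triu_indices(10, 1)]
        np.testing.assert_allclose(coph, expected, atol=1e-9)

    def test_ward_d1_variant_heights(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0.2, 1.8, (6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        d1 = gc.ward_tree(frame(d), criterion="ward.D1")
        d2_on_sqrt = gc.ward_tree(frame(np.sqrt(d)))
        np.testing.assert_allclose(d1.linkage[:, 2], d2_on_sqrt.linkage[:, 2] ** 2,
                                   atol=1e-9)

    def test_newick_export_parses(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0)
        nwk = gc.ward_tree(frame(d)).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2
        from io import StringIO

        from Bio import Phylo

        clade = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in clade.get_terminals()) == ["f0", "f1", "f2"]

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            gc.ward_tree(frame(np.zeros((1, 1))))


def enumeration_permanova_p(d, groups):
    """Full-enumeration oracle: F from first principles over all relabelings."""
    from itertools import permutations

    def f_stat(labels):
        labels = np.asarray(labels)
        n = len(labels)
        uniq = sorted(set(labels))
        ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in uniq:
            idx = [i for i in range(n) if labels[i] == g]
            ss_within += sum(
                d[i, j] ** 2 for i in idx for j in idx if i < j
            ) / len(idx)
        k = len(uniq)
        return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))

    obs = f_stat(groups)
    perms = sorted(set(permutations(groups)))
    count = sum(f_stat(p) >= obs - 1e-12 for p in perms)
    return count / len(perms)


class TestPermanova:
    def test_default_permutations(self):
        import inspect

        assert inspect.signature(gc.permanova).parameters["n_perm"].default == 9_999

    @pytest.mark.parametrize("n,sizes", [(4, (2, 2)), (5, (2, 3)), (6, (3, 3))])
    def test_exhaustive_matches_enumeration_oracle(self, n, sizes):
        rng = np.random.default_rng(n)
        for _ in range(5):
            m = rng.uniform(0.1, 2, (n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            groups = np.array(["a"] * sizes[0] + ["b"] * sizes[1])
            _, p = gc.permanova(d, groups, n_perm=9_999, seed=0)
            assert p == pytest.approx(enumeration_permanova_p(d, groups), abs=1e-12)

    def test_exhaustive_two_of_two_p_values(self):
        rng = np.random.default_rng(9)
        seen = set()
        for trial in range(10):
            m = rng.uniform(0.1, 2, (4, 4))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            _, p = gc.permanova(d, np.array(["a", "a", "b", "b"]), n_perm=999, seed=0)
            seen.add(round(p, 6))
        assert seen <= {round(1 / 3, 6), round(2 / 3, 6), 1.0}

    def test_f_invariant_to_within_group_relabeling(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.1, 2, (10, 10))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        f1, _ = gc.permanova(d, groups, n_perm=99, seed=0)
        order = np.r_[rng.permutation(5), 5 + rng.permutation(5)]
        f2, _ = gc.permanova(d[np.ix_(order, order)], groups[order], n_perm=99, seed=0)
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_matches_skbio_f_statistic(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        t = rng.integers(1, 50, (12, 6)).astype(float)
        d = gc.bray_curtis(pd.DataFrame(t, index=[f"s{i}" for i in range(12)]))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        f, _ = gc.permanova(d, groups, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)), groups,
            permutations=99,
        )
        assert f == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_null_type_one_error_calibrated(self):
        # exchangeable labels: rejection rate at .05 stays near nominal
        rng = np.random.default_rng(4)
        rejections = 0
        n_sets = 1_000
        for i in range(n_sets):
            m = rng.uniform(0.1, 2, (12, 12))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            groups = np.array(["a"] * 6 + ["b"] * 6)
            _, p = gc.permanova(d, groups, n_perm=199, seed=rng.integers(2**31))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sets <= 0.07

    def test_degenerate_groupings_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            gc.permanova(d, np.array(["a"] * 4))
        with pytest.raises(ValueError):
            gc.permanova(d, np.array(["a", "b", "c", "d"])[:4][np.r_[0, 0, 0, 0]])


class TestSplitCags:
    def _block_distance(self, seed=0, n_per=10, blocks=2, within=0.1, between=1.8):
        rng = np.random.default_rng(seed)
        n = n_per * blocks
        d = np.full((n, n), between) + rng.normal(0, 0.02, (n, n))
        for b in range(blocks):
            s = slice(b * n_per, (b + 1) * n_per)
            d[s, s] = within + rng.normal(0, 0.02, (n_per, n_per))
        d = np.clip((d + d.T) / 2, 0.01, None)
        np.fill_diagonal(d, 0)
        return frame(d)

    def test_two_planted_blocks_give_two_cags(self):
        d = self._block_distance()
        a = gc.split_cags(gc.ward_tree(d), d, alpha=0.05, n_perm=199, seed=0)
        assert a.n_cags == 2
        left = set(a.labels.iloc[:10])
        assert len(left) == 1 and left != set(a.labels.iloc[10:])

    def test_monotone_cag_count_in_alpha(self):
        d = self._block_distance(seed=3, blocks=3, within=0.4, between=1.2)
        counts = [
            gc.split_cags(gc.ward_tree(d), d, alpha=a, n_perm=199, seed=5).n_cags
            for a in (1e-4, 1e-2, 0.2)
        ]
        assert counts == sorted(counts)

    def test_deterministic_for_fixed_seed(self):
        d = self._block_distance(seed=1)
        a1 = gc.split_cags(gc.ward_tree(d), d, alpha=0.05, n_perm=199, seed=11)
        a2 = gc.split_cags(gc.ward_tree(d), d, alpha=0.05, n_perm=199, seed=11)
        pd.testing.assert_series_equal(a1.labels, a2.labels)
        assert [(r.node_id, r.decision) for r in a1.records] == [
            (r.node_id, r.decision) for r in a2.records
        ]

    def test_records_cover_cag_roots(self):
        d = self._block_distance(seed=2)
        a = gc.split_cags(gc.ward_tree(d), d, alpha=0.05, n_perm=199, seed=0)
        assert all(r.decision in {"split", "stop", "untestable"} for r in a.records)
        assert set(a.labels.index) == set(d.columns)

    def test_alpha_out_of_range(self):
        d = self._block_distance()
        with pytest.raises(ValueError):
            gc.split_cags(gc.ward_tree(d), d, alpha=1.5)


class TestCagAbundance:
    def _assignment(self, columns, labels):
        n = len(columns)
        d = frame(np.ones((n, n)) - np.eye(n), ids=list(columns))
        return gc.CagAssignment(
            labels=pd.Series(labels, index=columns, name="cag"),
            tree=gc.ward_tree(d),
        )

    def test_single_cag_equals_row_totals(self, small_table):
        a = self._assignment(small_table.columns, ["CAG1"] * 8)
        out = gc.cag_abundance(small_table, a)
        np.testing.assert_array_equal(out["CAG1"], small_table.sum(axis=1))

    def test_singletons_permute_columns(self, small_table):
        a = self._assignment(small_table.columns, [f"CAG{i+1}" for i in range(8)])
        out = gc.cag_abundance(small_table, a)
        assert sorted(map(tuple, out.T.values.tolist())) == sorted(
            map(tuple, small_table.T.values.tolist())
        )

    def test_conserves_assigned_reads_exactly(self, small_table):
        a = self._assignment(small_table.columns[:5], ["CAG1", "CAG1", "CAG2", "CAG2", "CAG2"])
        out = gc.cag_abundance(small_table, a)
        np.testing.assert_array_equal(
            out.sum(axis=1), small_table.iloc[:, :5].sum(axis=1)
        )

    def test_empty_intersection_rejected(self, small_table):
        a = self._assignment(["x1", "x2"], ["CAG1", "CAG1"])
        with pytest.raises(ValueError):
            gc.cag_abundance(small_table, a)


class TestNetworkEdges:
    def _setup(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        t = pd.DataFrame(
            {
                "a": np.abs(base) + 1,
                "b": np.abs(base) + 1,  # duplicate of a
                "c": rng.uniform(1, 2, 20),
            },
            index=[f"s{i}" for i in range(20)],
        )
        c = pd.DataFrame(
            [[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]],
            index=t.columns, columns=t.columns,
        )
        d = gc.corr_to_distance(c)
        labels = pd.Series(["CAG1", "CAG1", "CAG2"], index=t.columns, name="cag")
        assignment = gc.CagAssignment(labels=labels, tree=gc.ward_tree(d))
        return t, c, assignment

    def test_strict_threshold_drops_exact_boundary(self):
        t, c, a = self._setup()
        edges, _ = gc.network_edges(c, a, min_abs=0.5, table=t)
        feature_edges = edges[edges.level == "feature"]
        assert set(zip(feature_edges.a, feature_edges.b)) == {("a", "b")}

    def test_max_threshold_keeps_only_duplicates(self):
        t, c, a = self._setup()
        edges, _ = gc.network_edges(c, a, min_abs=1.0, table=t)
        assert len(edges) == 0  # r = 1.0 is not strictly above 1.0

    def test_node_annotations_and_hidden_flag(self):
        t, c, a = self._setup()
        _, nodes = gc.network_edges(c, a, min_abs=0.5, min_mean_abund=0.9, table=t)
        assert set(nodes.cag) == {"CAG1", "CAG2"}
        assert nodes.hidden.all()  # no CAG exceeds 90% mean relative abundance
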