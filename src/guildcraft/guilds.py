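"""Co-abundance group (guild) inference.

Features (ASVs) are clustered on their 1 - r correlation distance with Ward's
hierarchical method; PERMANOVA is then applied consecutively from the top of
the tree, testing each internal node's two child clades as groups, and
recursion stops where a split is not significant — the remaining subtree
becomes one co-abundance group (CAG).  CAG abundance is the sum of member
ASV abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ward tree
# ---------------------------------------------------------------------------

@dataclass
class WardTree:
    """Binary merge tree over features: scipy linkage matrix plus leaf ids."""

    ids: list[str]
    linkage: np.ndarray
    criterion: str = "ward.D2"

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(root, root.dist) + ";"


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    values = d.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if (values < -1e-8).any():
        raise ValueError("distance matrix must be non-negative")
    values = np.clip((values + values.T) / 2.0, 0, None)
    np.fill_diagonal(values, 0.0)
    return values


def ward_tree(d: pd.DataFrame, criterion: str = "ward.D2") -> WardTree:
    """Ward hierarchical clustering of a distance matrix.

    ``ward.D2`` (default) applies Ward's minimum-variance update to the
    distances as given — the behaviour of R's ``hclust(..., "ward.D2")`` and
    scipy's ``ward``.  ``ward.D1`` updates with unsquared distances; it is
    obtained by clustering sqrt(d) and squaring the merge heights.
    """
    values = _check_distance(d)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two features to build a tree")
    condensed = values[np.triu_indices(n, 1)]
    if criterion == "ward.D2":
        linkage = hierarchy.linkage(condensed, method="ward")
    elif criterion == "ward.D1":
        linkage = hierarchy.linkage(np.sqrt(condensed), method="ward")
        linkage = linkage.copy()
        linkage[:, 2] = linkage[:, 2] ** 2
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return WardTree(ids=[str(c) for c in d.columns], linkage=linkage, criterion=criterion)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f_terms(d2: np.ndarray) -> float:
    """Total sum of squares from a squared-distance matrix."""
    n = d2.shape[0]
    return d2.sum() / (2.0 * n)


def _f_from_groups(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    n, k = onehot.shape
    ss_total = _pseudo_f_terms(d2)
    ss_within = 0.0
    for g in range(k):
        idx = onehot[:, g].astype(bool)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * sizes[g])
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    d: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 9_999,
    seed=None,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA (pseudo-F and permutation p-value).

    Partitions the squared distances into between- and within-group sums
    (Anderson's formulation): F = (SS_b/(k-1)) / (SS_w/(n-k)).  The p-value
    is (1 + #{permuted F >= observed}) / (1 + n_perm) under random label
    permutations; when the number of distinct relabelings is at most
    ``n_perm`` every distinct relabeling is enumerated instead and
    p = #{F >= observed} / #relabelings (the identity included).
    """
    values = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    labels = np.asarray(groups)
    n = values.shape[0]
    if labels.shape[0] != n:
        raise ValueError("groups length must match distance matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes == n).any():
        raise ValueError("a group equals the full set")
    d2 = values**2

    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    f_obs = _f_from_groups(d2, onehot, sizes)

    n_distinct = factorial(n)
    for s in sizes:
        n_distinct //= factorial(int(s))

    if n_distinct <= n_perm:
        if k == 2:
            perm_codes = [
                np.isin(np.arange(n), c).astype(int)
                for c in combinations(range(n), int(sizes[1]))
            ]
        else:
            perm_codes = [np.array(pc) for pc in sorted(set(permutations(codes.tolist())))]
        f_perm = np.array(
            [_f_from_groups(d2, _onehot(pc, k), sizes) for pc in perm_codes]
        )
        p = float((f_perm >= f_obs - 1e-12).sum()) / len(perm_codes)
        return float(f_obs), p

    rng = np.random.default_rng(seed)
    if k == 2:
        # vectorized two-group permutations: within-group sums via masked matmul
        S = np.zeros((n_perm, n))
        for i in range(n_perm):
            S[i, rng.permutation(n)[: sizes[1]]] = 1.0
        row_tot = d2.sum(axis=0)
        grand = d2.sum()
        SA = S @ d2
        q1 = (SA * S).sum(axis=1)                      # group-1 block sum
        q0 = grand - 2.0 * (S * row_tot).sum(axis=1) + q1
        ss_within = q1 / (2.0 * sizes[1]) + q0 / (2.0 * sizes[0])
        ss_total = grand / (2.0 * n)
        f_perm = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
    else:
        f_perm = np.empty(n_perm)
        for i in range(n_perm):
            pc = codes[rng.permutation(n)]
            f_perm[i] = _f_from_groups(d2, _onehot(pc, k), sizes)
    p = (1.0 + float((f_perm >= f_obs - 1e-12).sum())) / (1.0 + n_perm)
    return float(f_obs), p


def _onehot(codes, k) -> np.ndarray:
    codes = np.asarray(codes)
    out = np.zeros((codes.size, k))
    out[np.arange(codes.size), codes] = 1.0
    return out


# ---------------------------------------------------------------------------
# recursive clade splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitRecord:
    """PERMANOVA record for one tested internal node."""

    node_id: int
    n_members: int
    child_sizes: tuple[int, int]
    f: float
    p: float
    n_perm: int
    decision: str  # "split", "stop", "untestable"


@dataclass
class CagAssignment:
    """Feature -> CAG label partition with the per-split test trail."""

    labels: pd.Series  # index: feature ids, values: CAG labels
    tree: WardTree
    records: list[SplitRecord] = field(default_factory=list)

    @property
    def n_cags(self) -> int:
        return self.labels.nunique()

    def members(self, cag: str) -> list[str]:
        return self.labels.index[self.labels == cag].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature-id": self.labels.index, "cag": self.labels.values})


def _distinct_splits(n1: int, n2: int) -> int:
    """Distinct unordered two-group partitions of n1+n2 items into sizes n1, n2."""
    c = comb(n1 + n2, n1)
    return c // 2 if n1 == n2 else c


def _split_f(d2: np.ndarray, mask: np.ndarray) -> float:
    """Pseudo-F of a binary split given the squared-distance matrix."""
    sizes = np.array([int((~mask).sum()), int(mask.sum())])
    onehot = np.zeros((d2.shape[0], 2))
    onehot[:, 1] = mask
    onehot[:, 0] = ~mask
    return _f_from_groups(d2, onehot, sizes)


def _node_split_test(
    sub: np.ndarray,
    left_mask: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float, int]:
    """Selection-aware empirical test of one Ward node's top split.

    The observed statistic is the pseudo-F of the node's two child clades.
    Because those children are themselves the Ward-optimal division of the
    node's distance sub-matrix, comparing F against free label permutations
    would be anti-conservative; instead each permutation shuffles the node's
    condensed distances, re-runs Ward on the shuffled matrix and scores the
    F of *that* tree's own top split — the same selection applied to
    structure-free data.  The loop stops early once the count of permuted
    F >= observed guarantees p >= alpha (the decision is then settled).

    Returns (observed F, p, permutations used).
    """
    m = sub.shape[0]
    d2 = sub**2
    f_obs = _split_f(d2, left_mask)
    iu = np.triu_indices(m, 1)
    condensed = sub[iu]
    count = 0
    done = 0
    for i in range(n_perm):
        shuffled = condensed[rng.permutation(condensed.size)]
        linkage = hierarchy.linkage(shuffled, method="ward")
        top = hierarchy.fcluster(linkage, 2, criterion="maxclust")
        square = np.zeros((m, m))
        square[iu] = shuffled
        square += square.T
        f_perm = _split_f(square**2, top == 2)
        count += int(f_perm >= f_obs - 1e-12)
        done = i + 1
        if (1.0 + count) / (1.0 + n_perm) >= alpha:
            break  # p can only grow; the split is already non-significant
    p = (1.0 + count) / (1.0 + done)
    return float(f_obs), float(p), done


def split_cags(
    tree: WardTree,
    d: pd.DataFrame,
    alpha: float = 0.001,
    n_perm: int = 9_999,
    seed=None,
    table: pd.DataFrame | None = None,
) -> CagAssignment:
    """Cut the Ward tree into CAGs by top-down PERMANOVA clade testing.

    Depth-first from the root: each internal node's two child clades form a
    candidate split of the distance sub-matrix of the node's members,
    scored by the PERMANOVA pseudo-F.  Significance comes from a
    selection-aware empirical null (see ``_node_split_test``): permutations
    shuffle the node's pairwise distances and re-run Ward, so the observed
    Ward-optimal split is compared against equally optimized splits of
    structure-free data.  If p < ``alpha`` the split is accepted and both
    children are recursed into; otherwise the node's member set becomes one
    CAG.  Nodes too small for the permutation granularity to reach
    significance (factorial(C(m,2)) < 1/alpha) are declared CAGs without
    testing.

    CAGs are labeled ``CAG1..CAGk`` in decreasing mean abundance when a
    feature ``table`` is supplied, otherwise in tree (left-to-right) order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    values = _check_distance(d)
    ids = [str(c) for c in d.columns]
    if ids != tree.ids:
        raise ValueError("tree was not built on this distance matrix")
    base_seed = np.random.default_rng(seed).integers(2**31)
    root = hierarchy.to_tree(tree.linkage)

    records: list[SplitRecord] = []
    cag_member_sets: list[list[int]] = []

    def testable(m: int) -> bool:
        pairs = comb(m, 2)
        if pairs > 20:  # factorial(21) already exceeds any sensible 1/alpha
            return True
        return factorial(pairs) >= 1.0 / alpha

    def visit(node):
        if node.is_leaf():
            cag_member_sets.append([node.id])
            return
        members = node.pre_order(lambda leaf: leaf.id)
        left = set(node.left.pre_order(lambda leaf: leaf.id))
        n1, n2 = len(left), len(members) - len(left)
        if not testable(len(members)):
            records.append(
                SplitRecord(node.id, len(members), (n1, n2), float("nan"), float("nan"),
                            0, "untestable")
            )
            cag_member_sets.append(members)
            return
        sub = values[np.ix_(members, members)]
        left_mask = np.array([m in left for m in members])
        # per-node RNG keyed on the node id: decisions are reproducible and
        # monotone in alpha for a fixed seed
        node_rng = np.random.default_rng((int(base_seed), int(node.id)))
        f, p, used = _node_split_test(sub, left_mask, alpha, n_perm, node_rng)
        if p < alpha:
            records.append(SplitRecord(node.id, len(members), (n1, n2), f, p, used, "split"))
            visit(node.left)
            visit(node.right)
        else:
            records.append(SplitRecord(node.id, len(members), (n1, n2), f, p, used, "stop"))
            cag_member_sets.append(members)

    visit(root)

    if table is not None:
        means = table.mean(axis=0)
        order = sorted(
            range(len(cag_member_sets)),
            key=lambda i: -float(means.iloc[cag_member_sets[i]].sum()),
        )
    else:
        order = list(range(len(cag_member_sets)))
    labels = pd.Series(index=pd.Index(ids, name="feature-id"), dtype=object)
    for rank, i in enumerate(order, start=1):
        for m in cag_member_sets[i]:
            labels.iloc[m] = f"CAG{rank}"
    return CagAssignment(labels=labels, tree=tree, records=records)


# ---------------------------------------------------------------------------
# CAG abundance and network export
# ---------------------------------------------------------------------------

def cag_abundance(table: pd.DataFrame, assignment: CagAssignment) -> pd.DataFrame:
    """Per-sample CAG abundance = sum of member feature abundances."""
    shared = [f for f in assignment.labels.index if f in table.columns]
    if not shared:
        raise ValueError("no assigned features present in the table")
    labels = assignment.labels.loc[shared]
    cags = sorted(labels.unique(), key=lambda c: int(str(c).replace("CAG", "") or 0))
    out = pd.DataFrame(
        {c: table[labels.index[labels == c]].sum(axis=1) for c in cags},
        index=table.index,
    )
    out.columns.name = None
    return out


def network_edges(
    c: pd.DataFrame,
    assignment: CagAssignment,
    min_abs: float = 0.5,
    min_mean_abund: float = 0.01,
    table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature- and CAG-level co-abundance network edges.

    Feature edges keep pairs with |r| strictly above ``min_abs``.  CAG-level
    edges carry the mean correlation over the inter-CAG feature pairs, kept
    by the same strict threshold.  Node annotations report mean relative
    abundance (from ``table`` when given); CAG nodes whose mean relative
    abundance is at most ``min_mean_abund`` are flagged hidden for plotting.
    """
    if not (0 <= min_abs <= 1 and 0 <= min_mean_abund <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    r = c.to_numpy(dtype=float)
    feats = [str(x) for x in c.columns]
    labels = assignment.labels

    rows = []
    for i, j in combinations(range(len(feats)), 2):
        if abs(r[i, j]) > min_abs:
            rows.append(
                {
                    "level": "feature",
                    "a": feats[i],
                    "b": feats[j],
                    "cag_a": labels.get(feats[i]),
                    "cag_b": labels.get(feats[j]),
                    "r": r[i, j],
                    "sign": "positive" if r[i, j] > 0 else "negative",
                }
            )
    cags = sorted(labels.unique())
    for a, b in combinations(cags, 2):
        ia = [feats.index(f) for f in labels.index[labels == a] if f in feats]
        ib = [feats.index(f) for f in labels.index[labels == b] if f in feats]
        if not ia or not ib:
            continue
        mean_r = float(r[np.ix_(ia, ib)].mean())
        if abs(mean_r) > min_abs:
            rows.append(
                {
                    "level": "cag",
                    "a": a,
                    "b": b,
                    "cag_a": a,
                    "cag_b": b,
                    "r": mean_r,
                    "sign": "positive" if mean_r > 0 else "negative",
                }
            )
    edges = pd.DataFrame(rows, columns=["level", "a", "b", "cag_a", "cag_b", "r", "sign"])

    nodes = []
    if table is not None:
        rel = table.div(table.sum(axis=1), axis=0)
        for cag in cags:
            members = [f for f in labels.index[labels == cag] if f in table.columns]
            mean_ab = float(rel[members].sum(axis=1).mean()) if members else 0.0
            nodes.append(
                {"cag": cag, "mean_rel_abundance": mean_ab, "hidden": mean_ab <= min_mean_abund}
            )
    node_df = pd.DataFrame(nodes, columns=["cag", "mean_rel_abundance", "hidden"])
    return edges, node_df
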