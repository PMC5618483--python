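"""Multiple alignment, neighbor-joining phylogeny and group assignment.

The aligner is a classic progressive scheme: a UPGMA guide tree built from
pairwise global-alignment identities, then profile-profile merges under
BLOSUM62 with affine gaps (Needleman-Wunsch-Gotoh on column-frequency
profiles).  Distances between aligned sequences are p-distances (fraction of
mismatched residues over compared columns, gap-containing columns excluded
pairwise).  Trees come from the Saitou-Nei neighbor-joining agglomeration
with the Studier-Keppler Q-criterion; node robustness from bootstrap
resampling of alignment columns.  Family members are assigned to groups by
their nearest reference leaf (patristic distance), with a consistency flag
from the smallest reference-containing clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import ScoringScheme, pairwise_identity

GAP = "-"
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX" + GAP


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))

    def subsample_columns(self, cols: Sequence[int]) -> "MultipleAlignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return MultipleAlignment(list(self.ids), rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        self.matrix = m


class TreeNode:
    """Rooted representation of the (unrooted) NJ tree; the root is the
    final trifurcation."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name: str | None = None,
                 children: list[tuple["TreeNode", float]] | None = None):
        self.name = name
        self.children: list[tuple[TreeNode, float]] = children or []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, digits: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.{digits}g}"
                             for c, bl in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"
        return fmt(self) + ";"


@dataclass
class PhyloTree:
    root: TreeNode
    negative_branches_clamped: bool = False

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        return self.root.to_newick()

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions, each as the frozenset of leaf names on
        the side not containing the lexicographically smallest leaf."""
        all_leaves = set(self.leaves())
        anchor = min(all_leaves)
        parts: set[frozenset] = set()

        def walk(node: TreeNode) -> set:
            below = set()
            for child, _ in node.children:
                sub = walk(child)
                below |= sub
                if 2 <= len(sub) <= len(all_leaves) - 2:
                    side = sub if anchor not in sub else all_leaves - sub
                    parts.add(frozenset(side))
            if node.is_leaf:
                return {node.name}
            return below

        walk(self.root)
        return parts

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix."""
        names: list[str] = []

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                names.append(node.name)
                return {node.name: 0.0}
            dists: dict[str, float] = {}
            groups = []
            for child, bl in node.children:
                sub = walk(child)
                sub = {k: v + bl for k, v in sub.items()}
                groups.append(sub)
                dists.update(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            pair_dists[(a, b)] = pair_dists[(b, a)] = da + db
            return dists

        pair_dists: dict[tuple[str, str], float] = {}
        walk(self.root)
        n = len(names)
        mat = np.zeros((n, n))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    mat[i, j] = pair_dists[(a, b)]
        return names, mat


# ---------------------------------------------------------------------------
# progressive MSA


def _profile(rows: list[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(ALPHABET)}
    L = len(rows[0])
    prof = np.zeros((L, len(ALPHABET)))
    for r in rows:
        for j, c in enumerate(r):
            prof[j, idx[c]] += 1
    return prof / len(rows)


def _submatrix(scheme: ScoringScheme) -> np.ndarray:
    """ALPHABET x ALPHABET substitution scores; gap rows/cols are zero."""
    S = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            S[i, j] = scheme.matrix[a, b]
    return S


def _profile_align(rows_a: list[str], rows_b: list[str],
                   scheme: ScoringScheme) -> tuple[list[str], list[str], float]:
    """Needleman-Wunsch-Gotoh on frequency profiles; returns gapped rows and
    the alignment score."""
    go = scheme.gap_open + scheme.gap_extend   # first gapped column
    ge = scheme.gap_extend
    FA, FB = _profile(rows_a), _profile(rows_b)
    S21 = _submatrix(scheme)
    score = FA @ S21 @ FB.T                     # (LA, LB) column-pair scores
    la, lb = score.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)          # gap in B (vertical move)
    Iy = np.full((la + 1, lb + 1), NEG)          # gap in A (horizontal move)
    M[0, 0] = 0.0
    Ix[1:, 0] = -(go + ge * np.arange(la))
    Iy[0, 1:] = -(go + ge * np.arange(lb))
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + score[i - 1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge)
        Ix[i, 0] = -(go + ge * (i - 1))
        # horizontal scan: Iy[i, j] = max_{k<j} M[i, k] - go - (j-1-k)*ge
        t = M[i, :-1] + ge * np.arange(lb)
        run = np.maximum.accumulate(t)
        Iy[i, 1:] = run - go - ge * (np.arange(1, lb + 1) - 1)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    final = float([M[i, j], Ix[i, j], Iy[i, j]][state])
    out_a: list[int | None] = []
    out_b: list[int | None] = []
    eps = 1e-6
    while i > 0 or j > 0:
        if i == 0:
            out_a.append(None)
            out_b.append(j - 1)
            j -= 1
        elif j == 0:
            out_a.append(i - 1)
            out_b.append(None)
            i -= 1
        elif state == 0:  # aligned column pair
            out_a.append(i - 1)
            out_b.append(j - 1)
            i, j = i - 1, j - 1
            state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
        elif state == 1:  # column from A, gap in B
            out_a.append(i - 1)
            out_b.append(None)
            state = 0 if abs(Ix[i, j] - (M[i - 1, j] - go)) < eps else 1
            i -= 1
        else:             # column from B, gap in A
            out_a.append(None)
            out_b.append(j - 1)
            state = 0 if abs(Iy[i, j] - (M[i, j - 1] - go)) < eps else 2
            j -= 1
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(r[k] if k is not None else GAP for k in out_a)
             for r in rows_a]
    new_b = ["".join(r[k] if k is not None else GAP for k in out_b)
             for r in rows_b]
    return new_a, new_b, final


def _upgma_order(d: np.ndarray) -> tuple:
    """Nested-tuple merge order over leaf indices (UPGMA, average linkage)."""
    n = d.shape[0]
    clusters: dict[int, tuple] = {i: (i,) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    trees: dict[int, object] = {i: i for i in range(n)}
    nxt = n
    while len(clusters) > 1:
        (i, j), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = (trees[i], trees[j])
        si, sj = sizes[i], sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[tuple(sorted((nxt, k)))] = (si * dik + sj * djk) / (si + sj)
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        del clusters[i], clusters[j], trees[i], trees[j], sizes[i], sizes[j]
        clusters[nxt] = ()
        trees[nxt] = merged
        sizes[nxt] = si + sj
        nxt += 1
    return trees[nxt - 1]


def progressive_msa(proteins: Mapping[str, str],
                    scheme: ScoringScheme | None = None) -> MultipleAlignment:
    """Progressive multiple alignment (guide tree + profile merges)."""
    scheme = scheme or ScoringScheme()
    ids = list(proteins)
    seqs = [proteins[i].upper() for i in ids]
    if not ids:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return MultipleAlignment(ids, [seqs[0]])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(seqs[i], seqs[j], scheme)
    order = _upgma_order(d)

    def build(node) -> tuple[list[int], list[str]]:
        if isinstance(node, int):
            return [node], [seqs[node]]
        (li, lr), (ri, rr) = build(node[0]), build(node[1])
        new_l, new_r, _ = _profile_align(lr, rr, scheme)
        return li + ri, new_l + new_r
    idx, rows = build(order)
    # restore input order
    ordered = {k: r for k, r in zip(idx, rows)}
    return MultipleAlignment(ids, [ordered[i] for i in range(n)])


# ---------------------------------------------------------------------------
# distances


def pdistance_matrix(alignment: MultipleAlignment) -> DistanceMatrix:
    """p-distance with pairwise deletion of gap-containing columns."""
    if len(alignment.rows) < 2:
        raise ValueError("need at least two rows")
    arr = np.frombuffer("".join(alignment.rows).encode(), dtype="S1")
    arr = arr.reshape(len(alignment.rows), alignment.n_columns)
    gap = arr == GAP.encode()
    comparable = ~gap[:, None, :] & ~gap[None, :, :]
    mismatch = (arr[:, None, :] != arr[None, :, :]) & comparable
    ncomp = comparable.sum(axis=2)
    if (ncomp + np.eye(len(alignment.rows)) == 0).any():
        raise ValueError("a sequence pair shares no comparable columns")
    with np.errstate(invalid="ignore"):
        d = mismatch.sum(axis=2) / np.maximum(ncomp, 1)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(alignment.ids), d)


def mean_pairwise_identity(alignment: MultipleAlignment) -> float:
    dm = pdistance_matrix(alignment)
    n = len(dm.ids)
    iu = np.triu_indices(n, 1)
    return float(np.mean(1.0 - dm.matrix[iu]))


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Ties in Q break toward the smallest (i, j) pair in the current working
    order; negative branch lengths are clamped to zero and flagged.  For an
    additive input matrix the tree's path metric reproduces it exactly.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    d = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.ids]
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.min(Q)
        ties = np.argwhere(np.isclose(Q, best, rtol=0, atol=1e-12))
        i, j = min((int(a), int(b)) for a, b in ties if a < b)
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        parent = TreeNode(children=[(nodes[i], clamp(vi)),
                                    (nodes[j], clamp(vj))])
        keep = [k for k in range(m) if k not in (i, j)]
        dn = 0.5 * (d[i, keep] + d[j, keep] - d[i, j])
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)], dn[:, None]]),
                       np.hstack([dn, [0.0]])])
        nodes = [nodes[k] for k in keep] + [parent]
    # final trifurcation
    a, b, c = nodes
    va = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    vb = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    vc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    root = TreeNode(children=[(a, va), (b, vb), (c, vc)])
    return PhyloTree(root, negative_branches_clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_supports(alignment: MultipleAlignment, B: int = 1000,
                       seed: int = 0) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Column-resampling bootstrap supports for the NJ tree.

    The alignment is canonicalized (rows sorted by id) before resampling so
    supports do not depend on taxon input order.  Returns the tree built
    from the full alignment with supports (percent of replicates containing
    each internal bipartition) written onto its internal nodes.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    order = np.argsort(alignment.ids)
    canon = MultipleAlignment([alignment.ids[k] for k in order],
                              [alignment.rows[k] for k in order])
    tree = nj_tree(pdistance_matrix(canon))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = canon.n_columns
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep = canon.subsample_columns(cols)
        try:
            rep_tree = nj_tree(pdistance_matrix(rep))
        except ValueError:
            continue  # replicate with an incomparable pair
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / B for bp, c in counts.items()}

    all_leaves = set(tree.leaves())
    anchor = min(all_leaves)

    def annotate(node: TreeNode) -> set:
        below = set()
        for child, _ in node.children:
            sub = annotate(child)
            below |= sub
            if 2 <= len(sub) <= len(all_leaves) - 2:
                side = sub if anchor not in sub else all_leaves - sub
                child.support = supports.get(frozenset(side))
        return below if node.children else {node.name}

    annotate(tree.root)
    return tree, supports


# ---------------------------------------------------------------------------
# group assignment


@dataclass
class GroupAssignment:
    groups: dict[str, object]          # family leaf -> group label
    inconsistent: dict[str, bool] = field(default_factory=dict)
    reference_anchors: dict[object, list[str]] = field(default_factory=dict)

    def sizes(self) -> dict[object, int]:
        out: dict[object, int] = {}
        for g in self.groups.values():
            out[g] = out.get(g, 0) + 1
        return out


def assign_groups(tree: PhyloTree,
                  reference_labels: Mapping[str, object]) -> GroupAssignment:
    """Assign each non-reference leaf the group of its nearest reference.

    The nearest reference is measured by patristic distance; the consistency
    flag is set when the smallest clade containing the leaf plus at least one
    reference holds references of a different group than the one assigned.
    """
    leaves = tree.leaves()
    refs = [l for l in leaves if l in reference_labels]
    if not refs:
        raise ValueError("tree contains no reference leaves")
    missing = set(reference_labels) - set(leaves)
    if missing:
        raise ValueError(f"references missing from tree: {sorted(missing)}")
    names, pmat = tree.patristic_distances()
    pos = {n: k for k, n in enumerate(names)}
    groups: dict[str, object] = {}
    for leaf in leaves:
        if leaf in reference_labels:
            continue
        dists = [(pmat[pos[leaf], pos[r]], r) for r in refs]
        _, nearest = min(dists)
        groups[leaf] = reference_labels[nearest]

    # consistency: the smallest clade (bipartition side of any edge of the
    # unrooted tree) containing the leaf plus >=1 reference must hold
    # references of the assigned group only
    sides: list[frozenset] = []

    def collect(node: TreeNode) -> set:
        if node.is_leaf:
            return {node.name}
        below = set()
        for child, _ in node.children:
            sub = collect(child)
            sides.append(frozenset(sub))
            below |= sub
        return below

    collect(tree.root)
    all_leaves = frozenset(leaves)
    candidates = set(sides) | {all_leaves - s for s in sides}
    inconsistent: dict[str, bool] = {}
    for leaf, grp in groups.items():
        best: tuple[int, frozenset] | None = None
        for side in candidates:
            if leaf not in side:
                continue
            if not any(r in reference_labels for r in side):
                continue
            if best is None or len(side) < best[0]:
                best = (len(side), side)
        ref_groups = {reference_labels[r] for r in best[1]
                      if r in reference_labels}
        inconsistent[leaf] = ref_groups != {grp}

    anchors: dict[object, list[str]] = {}
    for r in refs:
        anchors.setdefault(reference_labels[r], []).append(r)
    return GroupAssignment(groups, inconsistent, anchors)
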