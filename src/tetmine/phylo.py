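"""Neighbor-joining phylogeny with nonparametric bootstrap support.

The NJ agglomeration follows Saitou & Nei's Q-criterion with deterministic
lexicographic tie-breaking; negative branch-length estimates are clamped to
zero with the deficit moved to the sibling edge. Bootstrap support is the
percentage of column-resampled alignments whose NJ tree contains each
internal bipartition.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import GAP, Alignment


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # % of bootstrap replicates, internal edges

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree stored with a (trifurcating) root node."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def to_newick(self) -> str:
        def fmt(node: TreeNode, bl: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            return body if bl is None else f"{body}:{bl:g}"

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        from Bio import Phylo

        bp = Phylo.read(_io.StringIO(text), "newick")

        def convert(clade) -> TreeNode:
            node = TreeNode(name=clade.name)
            if clade.clades:
                if clade.confidence is not None:
                    node.support = float(clade.confidence)
                elif clade.name is not None and re.fullmatch(r"\d+(\.\d+)?", clade.name):
                    node.support = float(clade.name)
                    node.name = None
                for child in clade.clades:
                    node.children.append((convert(child), child.branch_length or 0.0))
            return node

        return cls(root=convert(bp.root))

    def path_length_matrix(self) -> pd.DataFrame:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        leaves = self.leaf_names
        idx = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        D = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            for child, bl in node.children:
                sub = {k: v + bl for k, v in walk(child).items()}
                for a, da in sub.items():
                    for b, db in acc.items():
                        D[idx[a], idx[b]] = D[idx[b], idx[a]] = da + db
                acc.update(sub)
            return acc

        walk(self.root)
        return pd.DataFrame(D, index=leaves, columns=leaves)

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions, keyed by the leaf set on the child
        side normalized to exclude the lexicographically smallest leaf."""
        all_leaves = set(self.root.leaves())
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode):
            for child, _bl in node.children:
                if not child.is_leaf:
                    side = set(child.leaves())
                    if anchor in side:
                        side = all_leaves - side
                    if 1 < len(side) < len(all_leaves) - 1:
                        out[frozenset(side)] = child
                    walk(child)

        walk(self.root)
        return out


def nj_tree(distances: pd.DataFrame) -> PhyloTree:
    """Neighbor joining on a symmetric non-negative distance matrix.

    Ties in the Q-criterion are broken by lexicographic order of the pair's
    cluster representatives (smallest leaf id per cluster). Raises on NaN.
    """
    if not isinstance(distances, pd.DataFrame):
        raise TypeError("nj_tree expects a labeled pandas DataFrame")
    if distances.isna().any().any():
        raise ValueError("distance matrix contains NaN")
    ids = list(distances.index)
    if len(ids) < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    D = {(a, b): float(distances.loc[a, b]) for a in ids for b in ids}
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in ids}
    reps: dict[str, str] = {name: name for name in ids}  # cluster representative
    active = list(ids)
    counter = 0

    def d(a, b):
        return D[(a, b)]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * d(a, b) - r[a] - r[b]
                pair_key = tuple(sorted((reps[a], reps[b])))
                cand = (q, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _key, a, b = best
        la = d(a, b) / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = d(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        new_name = f"_u{counter}"
        counter += 1
        parent = TreeNode()
        parent.children = [(nodes[a], la), (nodes[b], lb)]
        nodes[new_name] = parent
        reps[new_name] = min(reps[a], reps[b])
        for k in active:
            if k in (a, b):
                continue
            dist = (d(a, k) + d(b, k) - d(a, b)) / 2
            D[(new_name, k)] = D[(k, new_name)] = max(0.0, dist)
        D[(new_name, new_name)] = 0.0
        active = [k for k in active if k not in (a, b)] + [new_name]

    a, b, c = sorted(active, key=lambda k: reps[k])
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    root = TreeNode()
    root.children = [(nodes[a], max(0.0, la)), (nodes[b], max(0.0, lb)),
                     (nodes[c], max(0.0, lc))]
    return PhyloTree(root=root)


def p_distance_matrix(aln: Alignment) -> pd.DataFrame:
    """Pairwise p-distances with pairwise gap deletion (columns with a gap
    in either row are skipped for that pair)."""
    arr = np.array([list(r) for r in aln.rows])
    n = len(aln.ids)
    D = np.zeros((n, n))
    gaps = arr == GAP
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~gaps[i] & ~gaps[j]
            nv = int(valid.sum())
            if nv == 0:
                dist = 0.0
            else:
                dist = float((arr[i][valid] != arr[j][valid]).sum()) / nv
            D[i, j] = D[j, i] = dist
    return pd.DataFrame(D, index=list(aln.ids), columns=list(aln.ids))


def bootstrap_support(
    aln: Alignment, n_reps: int = 1000, seed: int | None = None,
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports attached.

    Each replicate resamples alignment columns with replacement, rebuilds
    distances (p-distance, pairwise gap deletion) and the NJ tree; support
    on an internal edge is the percentage of replicates whose tree contains
    the same bipartition.
    """
    if len(aln.ids) < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    tree = nj_tree(p_distance_matrix(aln))
    biparts = tree.bipartitions()
    counts = {bp: 0 for bp in biparts}
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in aln.rows])
    ncols = arr.shape[1]
    ids = list(aln.ids)
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        sub = arr[:, cols]
        rep_aln = Alignment(ids=tuple(ids), rows=tuple("".join(r) for r in sub))
        rep_tree = nj_tree(p_distance_matrix(rep_aln))
        rep_biparts = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_biparts:
                counts[bp] += 1
    for bp, node in biparts.items():
        node.support = 100.0 * counts[bp] / n_reps
    return tree


def clades_at(tree: PhyloTree, min_support: float = 50.0) -> list[tuple[str, ...]]:
    """Maximal clades whose subtending internal edge has support at or
    above ``min_support`` (the conventional significance cut)."""
    out: list[tuple[str, ...]] = []

    def walk(node: TreeNode):
        for child, _bl in node.children:
            if not child.is_leaf and child.support is not None and child.support >= min_support:
                out.append(tuple(sorted(child.leaves())))
            else:
                walk(child)

    walk(tree.root)
    return sorted(out)
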