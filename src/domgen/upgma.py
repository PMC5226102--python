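"""UPGMA dendrograms with locus-bootstrap support and Newick export.

UPGMA (unweighted pair group method with arithmetic mean) repeatedly
merges the closest pair of clusters, averaging distances weighted by
cluster size, and places each merge node at half the merge distance —
yielding an ultrametric rooted tree.  Ties are broken deterministically
in favour of the lexicographically smallest pair of cluster leaf-label
minima, so results are reproducible across platforms.

Bootstrap support follows Felsenstein's procedure with the band locus as
the resampling unit: loci are resampled with replacement, the distance
matrix and UPGMA tree recomputed, and each internal edge's support is the
percentage of replicate trees containing the same leaf bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .band_data import BandMatrix
from .distances import DistanceMatrix, mrd_matrix, nei_li_distance_matrix

__all__ = [
    "TreeNode",
    "upgma",
    "bootstrap_support",
    "write_newick",
    "read_newick",
    "to_newick",
]


@dataclass
class TreeNode:
    """Rooted (binary for internal merges) tree node.

    ``height`` is the ultrametric height above the leaves; leaf heights
    are 0.  ``support`` is a bootstrap percentage in [0, 100] or None.
    """

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        """Yield every node, preorder."""
        yield self
        for c in self.children:
            yield from c.walk()

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets of internal edges (excluding root and leaves)."""
        all_leaves = self.leaf_names()
        parts = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            clade = node.leaf_names()
            if 1 < len(clade) < len(all_leaves):
                parts.add(clade)
        return parts


def upgma(d: DistanceMatrix) -> TreeNode:
    """Build the UPGMA dendrogram from a distance matrix.

    Cluster-to-cluster distance after merging i and j into u is the
    size-weighted average (n_i d_ik + n_j d_jk) / (n_i + n_j); the merge
    node's height is half the merge distance.  Tie-break: among pairs at
    the minimum distance, choose the pair whose (smallest-leaf-label,
    other-smallest-leaf-label) is lexicographically least.
    """
    if d.n < 2:
        raise ValueError("need at least two samples")
    if np.isnan(d.values).any():
        raise ValueError("NaN in distance matrix")
    dist = d.values.astype(float).copy()
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=lab) for i, lab in enumerate(d.labels)
    }
    sizes = {i: 1 for i in nodes}
    # min leaf label per active cluster, for the deterministic tie-break
    minlab = {i: lab for i, lab in enumerate(d.labels)}
    active = sorted(nodes)
    next_id = d.n
    n_total = d.n
    dist_full = np.full((2 * n_total - 1, 2 * n_total - 1), np.inf)
    dist_full[:n_total, :n_total] = dist

    while len(active) > 1:
        idx = np.asarray(active)
        sub = dist_full[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(len(idx), k=1)
        vals = sub[iu, ju]
        dmin = vals.min()
        ties = np.flatnonzero(vals == dmin)
        best = None
        for t in ties:
            i, j = int(idx[iu[t]]), int(idx[ju[t]])
            key_pair = tuple(sorted((minlab[i], minlab[j])))
            if best is None or key_pair < best[0]:
                best = (key_pair, i, j)
        _, i, j = best
        dij = float(dmin)
        u = TreeNode(height=dij / 2.0, children=[nodes[i], nodes[j]])
        uid = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist_full[uid, k] = dist_full[k, uid] = (
                sizes[i] * dist_full[i, k] + sizes[j] * dist_full[j, k]
            ) / (sizes[i] + sizes[j])
        nodes[uid] = u
        sizes[uid] = sizes[i] + sizes[j]
        minlab[uid] = min(minlab[i], minlab[j])
        active = [k for k in active if k not in (i, j)] + [uid]
    return nodes[active[0]]


_METRICS = {"nei_li": nei_li_distance_matrix, "mrd": mrd_matrix}


def bootstrap_support(
    m: BandMatrix,
    metric: str = "nei_li",
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """UPGMA tree on the full data, annotated with locus-bootstrap support.

    Resamples band loci (columns) with replacement ``n_reps`` times,
    recomputes the distance matrix and tree, and annotates each internal
    node of the full-data tree with the percentage of replicates whose
    tree contains the same leaf bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if m.n_loci < 2:
        raise ValueError("bootstrap needs at least two loci")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    make_dist = _METRICS[metric]
    tree = upgma(make_dist(m))
    counts: dict[frozenset[str], int] = {p: 0 for p in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, m.n_loci, size=m.n_loci)
        rep = BandMatrix(
            samples=list(m.samples),
            band_ids=[f"bs{i}" for i in range(m.n_loci)],
            primer_ids=[m.primer_ids[c] for c in cols],
            primer_types=[m.primer_types[c] for c in cols],
            values=m.values[:, cols],
        )
        rep_parts = upgma(make_dist(rep)).bipartitions()
        for p in counts:
            if p in rep_parts:
                counts[p] += 1
    for node in tree.walk():
        if not node.is_leaf and node is not tree:
            clade = node.leaf_names()
            if clade in counts:
                node.support = 100.0 * counts[clade] / n_reps
    return tree


# -- Newick ---------------------------------------------------------------

def _quote(label: str) -> str:
    if any(ch in label for ch in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: TreeNode) -> str:
    """Newick string with branch lengths; bootstrap supports become
    internal node labels."""

    def render(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(node.name)}:{length:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        label = "" if node.support is None else f"{node.support:.10g}"
        return f"({inner}){label}:{length:.10g}"

    if t.is_leaf:
        return f"{_quote(t.name)}:0;"
    inner = ",".join(render(c, t.height) for c in t.children)
    label = "" if t.support is None else f"{t.support:.10g}"
    return f"({inner}){label};"


def write_newick(t: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(t) + "\n")


def read_newick(path_or_string) -> TreeNode:
    """Parse a Newick string (or file path ending .nwk/.newick/.tree)
    produced by :func:`write_newick` back into a TreeNode."""
    s = path_or_string
    if isinstance(s, str) and not s.lstrip().startswith("(") and not s.rstrip().endswith(";"):
        with open(s) as fh:
            s = fh.read()
    elif not isinstance(s, str):
        with open(s) as fh:
            s = fh.read()
    s = s.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0

    def parse_label():
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    out.append(s[pos])
                    pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    def parse_node(parent_height_holder):
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child = parse_node(None)
                node.children.append(child)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = parse_label()
            if label:
                node.support = float(label)
        else:
            node.name = parse_label()
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            length = float(parse_label())
        node._length = length  # branch length to parent, heights fixed below
        return node

    root = parse_node(None)
    if s[pos] != ";":
        raise ValueError("trailing characters in Newick string")

    # convert branch lengths to ultrametric heights (leaves at 0)
    def depth_to_leaf(node):
        if node.is_leaf:
            return 0.0
        return max(getattr(c, "_length", 0.0) + depth_to_leaf(c) for c in node.children)

    def set_heights(node):
        node.height = depth_to_leaf(node)
        for c in node.children:
            set_heights(c)

    set_heights(root)
    for node in root.walk():
        if hasattr(node, "_length"):
            del node._length
    return root
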