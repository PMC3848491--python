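"""Band-sharing distances, neighbour joining, bootstrap support, rooting.

Individuals are compared as multilocus fingerprints: each allele observed at
a locus is a "band", pooled over loci into one presence/absence set per
individual (a per-locus-averaged variant is available).  Similarity is the
Dice coefficient 2*n_xy/(n_x + n_y) over shared bands and distance is one
minus it, which for fragment data is the classic restriction-fragment
band-sharing distance.  Trees are built by standard neighbour joining with
deterministic tie-breaking, bootstrap support comes from resampling loci
with replacement, and rooting places the root on an outgroup's pendant edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "nei_li_distance",
    "neighbor_joining",
    "bootstrap_support",
    "root_at",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal distance matrix over ordered ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])

    def to_phylip(self) -> str:
        lines = [str(len(self.ids))]
        for i, name in enumerate(self.ids):
            lines.append(name + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]))
        return "\n".join(lines) + "\n"


@dataclass
class TreeNode:
    """Rooted or unrooted-as-trifurcating-root tree node.

    ``support`` is a bootstrap percentage on the edge above this node
    (internal edges only).
    """

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> set[str]:
        return {lf.name for lf in self.leaves()}

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def find(self, name: str) -> "TreeNode":
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(f"no leaf named {name!r}")


def to_newick(node: TreeNode, include_support: bool = True) -> str:
    """Serialize with branch lengths; integer supports as internal labels."""

    def fmt(n: TreeNode) -> str:
        if n.is_leaf():
            return f"{n.name}:{n.length:.6g}"
        inner = ",".join(fmt(c) for c in n.children)
        label = ""
        if include_support and n.support is not None:
            label = str(int(round(n.support)))
        elif n.name:
            label = n.name
        return f"({inner}){label}:{n.length:.6g}"

    inner = ",".join(fmt(c) for c in node.children)
    label = node.name or ""
    return f"({inner}){label};"


# ---------------------------------------------------------------------------
# Band-sharing (Dice / Nei-Li) distances
# ---------------------------------------------------------------------------

def _band_sets(g: GenotypeMatrix, per_locus: bool):
    """Per individual: pooled set of (locus, allele) bands, or per-locus sets."""
    pooled = []
    for i in range(g.n_individuals):
        if per_locus:
            sets = []
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                sets.append(set() if a == MISSING else {int(a), int(b)})
            pooled.append(sets)
        else:
            bands = set()
            for j in range(g.n_loci):
                a, b = g.calls[i, j]
                if a != MISSING:
                    bands.add((j, int(a)))
                    bands.add((j, int(b)))
            pooled.append(bands)
    return pooled


def nei_li_distance(g: GenotypeMatrix, per_locus_average: bool = False) -> DistanceMatrix:
    """Band-sharing distance 1 - 2*n_xy/(n_x + n_y) between all individuals.

    By default bands are pooled over loci into one fragment set per
    individual.  With ``per_locus_average`` the Dice similarity is computed
    per shared-typed locus and averaged.  Every pair must share at least one
    locus typed in both.
    """
    sets = _band_sets(g, per_locus_average)
    typed = g.calls[:, :, 0] != MISSING
    n = g.n_individuals
    d = np.zeros((n, n))
    for i, k in itertools.combinations(range(n), 2):
        if not np.any(typed[i] & typed[k]):
            raise ValueError(
                f"individuals {g.individuals[i]!r} and {g.individuals[k]!r} "
                "share no typed locus"
            )
        if per_locus_average:
            sims = []
            for sa, sb in zip(sets[i], sets[k]):
                if sa and sb:
                    sims.append(2 * len(sa & sb) / (len(sa) + len(sb)))
            if not sims:
                raise ValueError(
                    f"individuals {g.individuals[i]!r} and {g.individuals[k]!r} "
                    "share no typed locus"
                )
            sim = float(np.mean(sims))
        else:
            sa, sb = sets[i], sets[k]
            if not sa or not sb:
                raise ValueError(
                    f"individuals {g.individuals[i]!r} and {g.individuals[k]!r} "
                    "share no typed locus"
                )
            sim = 2 * len(sa & sb) / (len(sa) + len(sb))
        d[i, k] = d[k, i] = 1.0 - sim
    return DistanceMatrix(g.individuals, d)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Q-matrix ties are broken by the lowest (row, col) index pair.  Negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    edge.  On an additive matrix the generating topology and path lengths
    are recovered exactly.  Returns an unrooted tree as a trifurcating root
    (bifurcating root for 2-3 taxa handled degenerately).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) among minima for determinism
        flat = np.argmin(q)
        best = q.flat[flat]
        ties = np.argwhere(np.isclose(q, best, rtol=0, atol=1e-12))
        ti, tj = min((int(a), int(b)) for a, b in ties if a < b)
        i, j = active[ti], active[tj]
        li = 0.5 * sub[ti, tj] + (r[ti] - r[tj]) / (2 * (m - 2))
        lj = sub[ti, tj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node
        new_d = 0.5 * (d[i, active] + d[j, active] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_d
        d[active, k] = new_d
        d[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        for idx, ln in zip((a, b, c), (la, lb, lc)):
            nodes[idx].length = float(max(ln, 0.0))
        return TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    a, b = active
    half = d[a, b] / 2.0
    nodes[a].length = float(half)
    nodes[b].length = float(half)
    return TreeNode(children=[nodes[a], nodes[b]])


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, rooting
# ---------------------------------------------------------------------------

def _bipartitions(root: TreeNode, all_leaves: frozenset[str]) -> set[frozenset[str]]:
    """Internal-edge splits, each canonicalized to the side not containing
    the lexicographically smallest leaf."""
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in root.postorder():
        if node is root or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue  # trivial split
        if ref in side:
            side = frozenset(all_leaves - side)
        splits.add(side)
    return splits


def bootstrap_support(g: GenotypeMatrix, B: int = 1000, seed: int | None = None,
                      per_locus_average: bool = False) -> TreeNode:
    """NJ tree with bootstrap support from resampling loci with replacement.

    Support on each internal edge is the percentage of ``B`` replicate trees
    (distance + NJ on a resampled locus set) containing the same bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if g.n_loci < 2:
        raise ValueError("need >= 2 loci to bootstrap")
    ref_tree = neighbor_joining(nei_li_distance(g, per_locus_average))
    leaves = frozenset(ref_tree.leaf_names())
    counts: dict[frozenset[str], int] = {s: 0 for s in _bipartitions(ref_tree, leaves)}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, g.n_loci, size=g.n_loci)
        rep = GenotypeMatrix(
            g.individuals, [f"L{t}" for t in range(g.n_loci)], g.calls[:, cols, :]
        )
        rep_tree = neighbor_joining(nei_li_distance(rep, per_locus_average))
        rep_splits = _bipartitions(rep_tree, leaves)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for node in ref_tree.postorder():
        if node is ref_tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if min(leaves) in side:
            side = frozenset(leaves - side)
        node.support = 100.0 * counts[side] / B
    return ref_tree


def _edge_list(root: TreeNode):
    """Undirected edges (parent-id, child-id, length, support) plus node map."""
    edges = []
    nodes = {}

    def walk(node: TreeNode, nid: int, counter: list[int]):
        nodes[nid] = node
        for c in node.children:
            counter[0] += 1
            cid = counter[0]
            edges.append((nid, cid, c.length, c.support))
            walk(c, cid, counter)

    walk(root, 0, [0])
    return edges, nodes


def root_at(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the outgroup's pendant edge (at its midpoint).

    The outgroup must be a leaf.  Leaf set, path lengths and internal-edge
    supports are preserved; rooting twice at the same outgroup is
    topologically idempotent.
    """
    edges, nodes = _edge_list(tree)
    out_id = next(
        (nid for nid, nd in nodes.items() if nd.is_leaf() and nd.name == outgroup),
        None,
    )
    if out_id is None:
        raise KeyError(f"no leaf named {outgroup!r}")
    adj: dict[int, list[tuple[int, float, float | None]]] = {i: [] for i in nodes}
    for a, b, ln, sup in edges:
        adj[a].append((b, ln, sup))
        adj[b].append((a, ln, sup))

    (nbr, plen, psup) = adj[out_id][0]

    def build(nid: int, parent: int, length: float, support) -> TreeNode:
        nd = nodes[nid]
        kids = [build(c, nid, ln, sup) for c, ln, sup in adj[nid] if c != parent]
        if kids and not nd.is_leaf() and len(kids) == 1:
            # suppress degree-2 node left over from a previous rooting
            kids[0].length += length
            return kids[0]
        return TreeNode(name=nd.name if nd.is_leaf() else None, length=length,
                        support=None if not kids else support, children=kids)

    half = plen / 2.0
    root = TreeNode(children=[
        build(out_id, nbr, half, None),
        build(nbr, out_id, half, psup),
    ])
    return root
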