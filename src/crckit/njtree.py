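"""Neighbor joining, bootstrap support, and unrooted-tree utilities.

A deliberately small, dependency-free tree representation: nodes are
integers, leaves carry taxon labels, edges carry lengths.  NJ follows the
Saitou-Nei Q-criterion; Q-ties are broken by the lexicographically
smallest (min label, max label) pair of cluster labels, where a cluster is
labelled by its smallest member taxon, so the topology is independent of
input order.  Negative branch lengths are clamped to zero with the deficit
moved to the sister branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_TIE_TOL = 1e-12


@dataclass
class Tree:
    """Unrooted tree: adjacency map node -> {neighbor: branch length}."""

    adj: dict = field(default_factory=dict)
    leaf_name: dict = field(default_factory=dict)  # node -> taxon label

    def add_edge(self, a: int, b: int, length: float):
        self.adj.setdefault(a, {})[b] = length
        self.adj.setdefault(b, {})[a] = length

    @property
    def leaves(self):
        return sorted(self.leaf_name.values())

    def bipartitions(self):
        """frozenset of taxa on one canonical side of each internal edge
        (the side not containing the smallest taxon), with branch length."""
        names = self.leaves
        if not names:
            return {}
        anchor = names[0]
        out = {}
        seen = set()
        for a in self.adj:
            for b, ln in self.adj[a].items():
                if (b, a) in seen:
                    continue
                seen.add((a, b))
                side = self._side(a, b)
                if len(side) < 2 or len(side) > len(names) - 2:
                    continue
                if anchor in side:
                    side = frozenset(n for n in names if n not in side)
                out[frozenset(side)] = ln
        return out

    def _side(self, a: int, b: int):
        """Taxa reachable from b without crossing edge (a,b)."""
        stack, seen, taxa = [b], {a, b}, []
        if b in self.leaf_name:
            taxa.append(self.leaf_name[b])
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    if y in self.leaf_name:
                        taxa.append(self.leaf_name[y])
                    stack.append(y)
        return set(taxa)

    def newick(self, supports: dict | None = None) -> str:
        """Newick string rooted at an arbitrary internal node; bipartition
        supports (percent) become internal node labels."""
        internal = [n for n in self.adj if n not in self.leaf_name]
        root = internal[0] if internal else next(iter(self.adj))
        names = self.leaves
        anchor = names[0] if names else ""

        def fmt(node, parent, length):
            kids = [k for k in self.adj[node] if k != parent]
            if not kids:
                return f"{self.leaf_name[node]}:{length:.6g}"
            inner = ",".join(fmt(k, node, self.adj[node][k]) for k in kids)
            label = ""
            if supports is not None and parent is not None:
                side = self._side(parent, node)
                key = frozenset(side)
                if anchor in side:
                    key = frozenset(n for n in names if n not in side)
                if key in supports:
                    label = f"{supports[key]:g}"
            if parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{length:.6g}"

        return fmt(root, None, 0.0) + ";"


def neighbor_joining(ids, d) -> Tree:
    """Saitou-Nei neighbor joining on distance matrix ``d`` over ``ids``."""
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.asarray(d, dtype=float).copy()
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    tree = Tree()
    for i, name in enumerate(ids):
        tree.leaf_name[i] = name
        tree.adj.setdefault(i, {})
    next_node = n
    active = list(range(n))
    labels = {i: ids[i] for i in range(n)}  # cluster label = min member taxon

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + _TIE_TOL)
        best = None
        for a, b in cand:
            if a >= b:
                continue
            la, lb = labels[active[a]], labels[active[b]]
            key = (min(la, lb), max(la, lb))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_node
        next_node += 1
        tree.add_edge(i, u, max(li, 0.0))
        tree.add_edge(j, u, max(lj, 0.0))
        labels[u] = min(labels[i], labels[j])
        newrow = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, : u] = newrow[: u]
        D[: u, u] = newrow[: u]
        D[u, u] = 0.0
        active = [x for x in active if x not in (i, j)] + [u]

    i, j, k = active
    # three-point formulas
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    u = next_node
    for node, ln in ((i, li), (j, lj), (k, lk)):
        tree.add_edge(node, u, max(ln, 0.0))
    return tree


def p_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise fraction of differing columns (gaps count as mismatches;
    a gap never matches anything, including another gap)."""
    n = mat.shape[0]
    D = np.zeros((n, n))
    gap = mat == 45  # '-'
    for i in range(n):
        diff = (mat[i] != mat) | gap | gap[i]
        D[i] = diff.mean(axis=1)
    np.fill_diagonal(D, 0.0)
    return D


def alignment_matrix(alignment):
    ids = [a for a, _ in alignment]
    L = {len(s) for _, s in alignment}
    if len(L) != 1:
        raise ValueError("alignment rows differ in length")
    mat = np.frombuffer("".join(s.upper() for _, s in alignment).encode(), dtype=np.uint8)
    return ids, mat.reshape(len(ids), L.pop()).copy()


def bootstrap_groups(alignment, n_reps: int, seed: int):
    """Bootstrap support (%) per internal bipartition of the NJ tree.

    ``alignment``: list of (id, aligned sequence).  Columns are resampled
    with replacement per replicate; NJ is rebuilt on p-distances.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids, mat = alignment_matrix(alignment)
    if len(ids) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    rng = np.random.default_rng(seed)
    L = mat.shape[1]
    ref_tree = neighbor_joining(ids, p_distance_matrix(mat))
    counts = {bp: 0 for bp in ref_tree.bipartitions()}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rmat = mat[:, cols]
        t = neighbor_joining(ids, p_distance_matrix(rmat))
        for bp in t.bipartitions():
            if bp in counts:
                counts[bp] += 1
            else:
                counts[bp] = counts.get(bp, 0) + 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return ref_tree, supports
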