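"""Distance-based phylogenetic placement of candidates among references.

Distances are p-distances on optimal pairwise global alignments
(Needleman-Wunsch, BLOSUM62, affine 11/1): d = 1 - identities/columns.
The tree is built by the Saitou-Nei Neighbor-Joining algorithm, implemented
here directly: at each step the pair minimising
Q(i, j) = (r - 2) d(i, j) - R_i - R_j is joined (ties broken by the smallest
index pair), branch lengths follow the standard two-point formulas, and
negative length estimates are clamped to zero and flagged, as MEGA does.
Query leaves are then scored by whether their nearest labelled reference
(path-length distance) shares the classifier's label.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np

from .homology import align_global
from .seqio import ProteinSequence


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("need a symmetric non-negative zero-diagonal matrix")
        object.__setattr__(self, "d", d)

    def to_phylip(self) -> str:
        lines = [f" {len(self.ids)}"]
        for i, name in enumerate(self.ids):
            row = " ".join(f"{x:.6f}" for x in self.d[i])
            lines.append(f"{name:<12s}{row}")
        return "\n".join(lines) + "\n"


class Node:
    """Tree node; ``length`` is the branch to the parent."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[list["Node"]] = None,
                 length: float = 0.0) -> None:
        self.name = name
        self.children = children or []
        self.length = length

    def leaves(self) -> list["Node"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        label = _quote(self.name) if self.name else ""
        if not self.children:
            return f"{label}:{self.length:.6f}"
        inner = ",".join(c._newick_node() for c in self.children)
        if self.length or label:
            return f"({inner}){label}:{self.length:.6f}"
        return f"({inner})"


def _quote(name: str) -> str:
    return f"'{name}'" if any(c in name for c in " ()[]:;,") else name


@dataclasses.dataclass
class PhyloTree:
    root: Node
    leaf_order: tuple[str, ...]
    clamped_branches: int = 0

    def newick(self) -> str:
        return self.root.newick()

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Path-length distance between every pair of leaves."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def walk(node: Node) -> int:
            nid = id(node)
            adj.setdefault(nid, [])
            if node.name and not node.children:
                names[nid] = node.name
            for c in node.children:
                cid = walk(c)
                adj[nid].append((cid, c.length))
                adj[cid].append((nid, c.length))
            return nid

        walk(self.root)
        out: dict[tuple[str, str], float] = {}
        for src, src_name in names.items():
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for dst, dst_name in names.items():
                if dst != src:
                    out[(src_name, dst_name)] = dist[dst]
        return out


def pdistance_matrix(seqs: Sequence[ProteinSequence]) -> DistanceMatrix:
    """Pairwise global-alignment p-distances (1 - identity fraction)."""
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_global(seqs[i], seqs[j])
            d[i, j] = d[j, i] = 1.0 - aln.identities / aln.aligned_columns
    return DistanceMatrix(tuple(s.id for s in seqs), d)


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining; unrooted, internal nodes of degree 3."""
    n = len(m.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: dict[int, Node] = {i: Node(name) for i, name in enumerate(m.ids)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(m.d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    clamped = 0

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        rowsum = {i: sum(d(i, k) for k in active) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d(i, j) - rowsum[i] - rowsum[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = d(i, j) - li
        ni, nj_ = nodes.pop(i), nodes.pop(j)
        ni.length, nj_.length = clamp(li), clamp(lj)
        new = Node(children=[ni, nj_])
        nodes[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(next_id, k), max(next_id, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = clamp(lk)
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, m.ids, clamped)


def cluster_concordance(tree: PhyloTree, query_labels: dict[str, str],
                        reference_labels: dict[str, str],
                        ) -> tuple[float, list[dict]]:
    """Fraction of queries whose nearest labelled leaf shares their label.

    Per query, the nearest reference by path length is found (ties broken
    toward the reference earliest in the matrix order, and flagged). A query
    whose nearest-reference distance exceeds the 95th percentile of
    reference-reference distances is flagged as a long branch.
    """
    if not query_labels or len(reference_labels) < 2:
        raise ValueError("need >=1 query and >=2 labelled references")
    paths = tree.leaf_path_lengths()
    order = {name: i for i, name in enumerate(tree.leaf_order)}
    refs = sorted(reference_labels, key=order.get)
    ref_ref = [paths[(r1, r2)] for i, r1 in enumerate(refs)
               for r2 in refs[i + 1:]]
    long_branch_cutoff = float(np.percentile(ref_ref, 95)) if ref_ref else 0.0

    rows = []
    hits = 0
    for q in sorted(query_labels, key=order.get):
        dists = [(paths[(q, r)], order[r], r) for r in refs]
        dmin, _, nearest = min(dists)
        tie = sum(1 for dd, _, _ in dists if abs(dd - dmin) < 1e-12) > 1
        concordant = reference_labels[nearest] == query_labels[q]
        hits += concordant
        rows.append({
            "query_id": q,
            "query_label": query_labels[q],
            "nearest_reference": nearest,
            "reference_label": reference_labels[nearest],
            "distance": round(dmin, 6),
            "concordant": concordant,
            "tie": tie,
            "long_branch": dmin > long_branch_cutoff,
        })
    return hits / len(query_labels), rows
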