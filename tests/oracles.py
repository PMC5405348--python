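"""Independent brute-force oracles used to validate the implementation.

Each oracle is deliberately naive (enumeration / textbook DP / least-squares
fits) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def orf_spans_bruteforce(seq: str, min_aa: int):
    """All (start, end, strand) forward-strand spans of qualifying ORFs.

    Enumerates every start/stop codon pair in all six frames, keeps the
    longest ORF per (strand, frame, stop), span includes the stop codon.
    """
    n = len(seq)
    out = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            starts = [p for p in range(frame, n - 2, 3) if s[p:p + 3] in STARTS]
            stops = [p for p in range(frame, n - 2, 3) if s[p:p + 3] in STOPS]
            for stop in stops:
                cands = [p for p in starts if p < stop
                         and not any(p < q < stop for q in stops)]
                if not cands:
                    continue
                start = min(cands)  # longest ORF for this stop
                if (stop - start) // 3 >= min_aa:
                    a, b = start, stop + 3
                    if strand == "-":
                        a, b = n - (stop + 3), n - start
                    out.add((a, b, strand))
    return out


def fuzzy_best_bruteforce(elements, seq: str, min_elements: int):
    """Best (mismatch fraction, coverage) over all window/element-block pairs.

    ``elements`` is a list of residue-sets (empty set = wildcard). Returns
    (fraction, coverage, window_start, element_start) of the best candidate,
    preferring low fraction, wide coverage, leftmost; or None.
    """
    n = len(elements)
    best = None
    for k in range(min_elements, n + 1):
        for es in range(0, n - k + 1):
            block = elements[es:es + k]
            for p in range(len(seq) - k + 1):
                mm = sum(1 for i, allowed in enumerate(block)
                         if allowed and seq[p + i] not in allowed)
                cand = (mm / k, -k, p, es)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    frac, negk, p, es = best
    return frac, -negk, p, es


def gotoh(a: str, b: str, sub, gap_open: float = 11.0,
          gap_extend: float = 1.0, local: bool = True) -> float:
    """Textbook Gotoh affine-gap DP; returns the optimal score.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend`` (matching PairwiseAligner's open/extend convention).
    """
    NEG = -1e9
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (deletion from a)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    if not local:
        for i in range(1, la + 1):
            X[i, 0] = -gap_open - (i - 1) * gap_extend
        for j in range(1, lb + 1):
            Y[0, j] = -gap_open - (j - 1) * gap_extend
    else:
        M[:, 0] = 0.0
        M[0, :] = 0.0
    best = 0.0 if local else NEG
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = sub[a[i - 1], b[j - 1]]
            diag = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            M[i, j] = max(diag, 0.0) if local else diag
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
            if local:
                best = max(best, M[i, j])
    if local:
        return best
    return max(M[la, lb], X[la, lb], Y[la, lb])


# --- tree oracles ---------------------------------------------------------


def random_unrooted_tree(n: int, rng: np.random.Generator):
    """Random unrooted binary tree as an edge dict {(u, v): length}.

    Leaves are 0..n-1; internal nodes get larger ids. Built by sequential
    leaf addition to random edges.
    """
    edges = {}
    nxt = n

    def add_edge(u, v, w):
        edges[(min(u, v), max(u, v))] = w

    def lengths(k):
        return rng.uniform(0.1, 1.0, size=k)

    add_edge(0, 1, float(rng.uniform(0.1, 1.0)))
    for leaf in range(2, n):
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = edges.pop((u, v))
        mid = nxt
        nxt += 1
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, float(lengths(1)[0]))
    return edges


def tree_distances(edges, n: int) -> np.ndarray:
    nodes = set()
    for u, v in edges:
        nodes.update((u, v))
    adj = {x: [] for x in nodes}
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    d = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n):
            d[src, dst] = dist[dst]
    return d


def splits_of_edges(edges, n: int) -> frozenset:
    """Non-trivial leaf bipartitions induced by the edges of an unrooted tree."""
    nodes = set()
    for u, v in edges:
        nodes.update((u, v))
    adj = {x: set() for x in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    splits = set()
    for u, v in edges:
        # leaves on u's side when edge (u,v) is cut
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != v and y not in seen and not (x == u and y == v):
                    seen.add(y)
                    stack.append(y)
        side = frozenset(w for w in seen if w < n)
        if 1 < len(side) < n - 1:
            splits.add(min(side, frozenset(range(n)) - side,
                           key=lambda s: (len(s), sorted(s))))
    return frozenset(splits)


def newick_splits(newick: str, leaf_names, skbio_module) -> frozenset:
    """Bipartitions of a newick string, via scikit-bio parsing."""
    idx = {name: i for i, name in enumerate(leaf_names)}
    n = len(leaf_names)
    tree = skbio_module.TreeNode.read([newick])
    splits = set()
    for node in tree.non_tips():
        side = frozenset(idx[t.name] for t in node.tips())
        if 1 < len(side) < n - 1:
            splits.add(min(side, frozenset(range(n)) - side,
                           key=lambda s: (len(s), sorted(s))))
    return frozenset(splits)


def enumerate_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1, as edge lists."""
    def grow(edges, next_leaf, next_internal):
        if next_leaf == n:
            yield list(edges)
            return
        for i in range(len(edges)):
            u, v = edges[i]
            mid = next_internal
            rest = edges[:i] + edges[i + 1:]
            new = rest + [(u, mid), (mid, v), (mid, next_leaf)]
            yield from grow(new, next_leaf + 1, next_internal + 1)

    start = [(0, n), (1, n), (2, n)]  # star on first three leaves
    yield from grow(start, 3, n + 1)


def fits_additively(edge_list, n: int, d: np.ndarray, tol: float = 1e-8):
    """Least-squares branch lengths for a topology; True iff exact fit."""
    nodes = sorted({x for e in edge_list for x in e})
    adj = {x: [] for x in nodes}
    for ei, (u, v) in enumerate(edge_list):
        adj[u].append((v, ei))
        adj[v].append((u, ei))
    rows, rhs = [], []
    for i in range(n):
        # DFS paths from leaf i recording edge incidence
        stack = [(i, [])]
        seen = {i}
        paths = {}
        while stack:
            x, path = stack.pop()
            paths[x] = path
            for y, ei in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, path + [ei]))
        for j in range(i + 1, n):
            row = np.zeros(len(edge_list))
            row[paths[j]] = 1.0
            rows.append(row)
            rhs.append(d[i, j])
    A = np.array(rows)
    b = np.array(rhs)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    return bool(np.allclose(A @ x, b, atol=tol)), x
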