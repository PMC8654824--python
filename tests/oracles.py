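"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written in plain Python (dict/loop style,
no numpy vectorisation, no imports from the package's numerical internals)
so it constitutes an independent path against which the implementation is
checked.
"""

from __future__ import annotations

import math
import random

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
PLAIN = {"A", "C", "G", "T"}


def oracle_pair_counts(a: str, b: str) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) by per-site loop."""
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in PLAIN or y not in PLAIN:
            continue
        n += 1
        if x == y:
            continue
        both_pur = x in PURINES and y in PURINES
        both_pyr = x in PYRIMIDINES and y in PYRIMIDINES
        if both_pur or both_pyr:
            ts += 1
        else:
            tv += 1
    return ts, tv, n


def oracle_k2p(a: str, b: str) -> float | None:
    """Closed-form K2P from per-site counts; None when undefined."""
    ts, tv, n = oracle_pair_counts(a, b)
    if n == 0:
        return None
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def oracle_pdist(a: str, b: str) -> float | None:
    ts, tv, n = oracle_pair_counts(a, b)
    if n == 0:
        return None
    return (ts + tv) / n


def oracle_match(
    seqs: dict[str, str],
    species: dict[str, str],
    threshold: float | None = None,
    dist=oracle_k2p,
) -> dict[str, str]:
    """O(n^2) BM/BCM classifier: query -> category string."""
    out: dict[str, str] = {}
    ids = sorted(seqs)
    for q in ids:
        cands = []
        for other in ids:
            if other == q:
                continue
            d = dist(seqs[q], seqs[other])
            if d is not None:
                cands.append((d, other))
        if not cands:
            out[q] = "EXCLUDED"
            continue
        best = min(d for d, _ in cands)
        if threshold is not None and best > threshold:
            out[q] = "NO_MATCH"
            continue
        best_species = {species[o] for d, o in cands if d == best}
        if best_species == {species[q]}:
            out[q] = "CORRECT"
        elif species[q] in best_species:
            out[q] = "AMBIGUOUS"
        else:
            out[q] = "INCORRECT"
    return out


def oracle_bcm_threshold(
    seqs: dict[str, str], species: dict[str, str], dist=oracle_k2p
) -> float:
    """Smallest intraspecific distance covering >= 95% of them, by sort."""
    ids = sorted(seqs)
    intra = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if species[a] == species[b]:
                d = dist(seqs[a], seqs[b])
                if d is not None:
                    intra.append(d)
    intra.sort()
    rank = math.ceil(0.95 * len(intra))
    return intra[rank - 1]


def random_additive_tree(
    n_leaves: int, rng: random.Random
) -> tuple[dict[str, dict[str, float]], set[frozenset[str]]]:
    """Random unrooted binary tree; returns (path-length matrix, splits).

    Built by sequential leaf attachment onto random edges; branch lengths
    uniform on [0.05, 1.0] so the matrix is strictly additive. Splits are
    the non-trivial bipartitions, each reported as its min-containing side.
    """
    # adjacency on node ids; leaves are "L0".."Lk", internals negative ints
    labels = [f"L{i}" for i in range(n_leaves)]
    adj: dict[object, dict[object, float]] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    blen = lambda: rng.uniform(0.05, 1.0)
    connect(labels[0], labels[1], blen())
    next_internal = -1
    for leaf in labels[2:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = rng.choice(sorted(edges, key=str))
        w = adj[u][v]
        mid = next_internal
        next_internal -= 1
        disconnect(u, v)
        split = rng.uniform(0.25, 0.75)
        connect(u, mid, w * split)
        connect(mid, v, w * (1 - split))
        connect(mid, leaf, blen())

    # all-pairs leaf distances by DFS
    dists: dict[str, dict[str, float]] = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node].items():
                if nb not in seen:
                    seen[nb] = seen[node] + w
                    stack.append(nb)
        dists[src] = {lbl: seen[lbl] for lbl in labels}

    # splits: removing each internal-internal edge partitions the leaves
    splits: set[frozenset[str]] = set()
    internals = [u for u in adj if isinstance(u, int)]
    seen_edges = set()
    for u in internals:
        for v in list(adj[u]):
            if not isinstance(v, int):
                continue
            key = frozenset((u, v))
            if key in seen_edges:
                continue
            seen_edges.add(key)
            side = set()
            stack = [u]
            visited = {u, v}
            while stack:
                node = stack.pop()
                if isinstance(node, str):
                    side.add(node)
                for nb in adj[node]:
                    if nb not in visited:
                        visited.add(nb)
                        stack.append(nb)
            if 2 <= len(side) <= n_leaves - 2:
                other = frozenset(set(labels) - side)
                splits.add(min(frozenset(side), other, key=sorted))
    return dists, splits


def normalise_splits(
    sides: set[frozenset[str]], all_leaves: frozenset[str]
) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions (min side by sorted order)."""
    out = set()
    for side in sides:
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(min(side, all_leaves - side, key=sorted))
    return out
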