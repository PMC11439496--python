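"""Independent brute-force oracles used by the test suite.

These deliberately avoid the dynamic-programming formulations they check:
local alignment is scored by enumerating matched-pair subsequences, trees
are scored by recomputing path-length metrics on independently generated
random trees, and profile scans are scored by enumerating every
profile-segment/sequence-segment placement.
"""

from itertools import combinations

import numpy as np

from b12screen.search import _INDEX, ScoringScheme


def sw_bruteforce(a: str, b: str, scheme: ScoringScheme) -> int:
    """Optimal local alignment score by exhaustive enumeration.

    A local alignment is determined by its matched columns: two equal-length
    increasing index subsequences.  Between consecutive matched pairs one
    side advances by exactly one position (canonical alignments: no adjacent
    opposite gap runs); the other side's surplus is a gap run charged
    open + (len-1) * extend.  The empty alignment scores 0.
    """
    S = scheme.substitution_matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    ea = [_INDEX[c] for c in a]
    eb = [_INDEX[c] for c in b]
    la, lb = len(ea), len(eb)
    best = 0
    for k in range(1, min(la, lb) + 1):
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                score = int(S[ea[ia[0]], eb[ib[0]]])
                ok = True
                for t in range(1, k):
                    da = ia[t] - ia[t - 1]
                    db = ib[t] - ib[t - 1]
                    if da > 1 and db > 1:
                        ok = False
                        break
                    g = max(da, db) - 1
                    if g:
                        score -= go + (g - 1) * ge
                    score += int(S[ea[ia[t]], eb[ib[t]]])
                if ok and score > best:
                    best = score
    return best


def random_additive_matrix(rng: np.random.Generator, n_tips: int):
    """A random binary tree with positive branch lengths, returned as its
    (labels, additive distance matrix) pair.

    The tree is built by sequential leaf attachment on an edge list and the
    metric recomputed by breadth-first traversal -- no code shared with the
    neighbour-joining implementation under test.
    """
    labels = [f"t{i}" for i in range(n_tips)]
    # adjacency: node -> list of (node, length); internal nodes are ints
    next_internal = [n_tips]
    adj: dict = {}

    def connect(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def blen():
        return float(rng.uniform(0.1, 1.0))

    connect(labels[0], "root", blen())
    connect(labels[1], "root", blen())
    connect(labels[2], "root", blen())
    edges = [(labels[0], "root"), (labels[1], "root"), (labels[2], "root")]
    for leaf in labels[3:]:
        u, v = edges[rng.integers(0, len(edges))]
        w = next(w for x, w in adj[u] if x == v)
        mid = next_internal[0]
        next_internal[0] += 1
        adj[u] = [(x, l) for x, l in adj[u] if x != v]
        adj[v] = [(x, l) for x, l in adj[v] if x != u]
        split = float(rng.uniform(0.05, w - 0.05)) if w > 0.1 else w / 2
        connect(u, mid, split)
        connect(v, mid, w - split)
        connect(leaf, mid, blen())
        edges.remove((u, v))
        edges.extend([(u, mid), (v, mid), (leaf, mid)])
    d = np.zeros((n_tips, n_tips))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    stack.append(nxt)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    np.fill_diagonal(d, 0.0)
    return labels, (d + d.T) / 2.0  # exact symmetry despite float order


def scan_bruteforce(profile_scores: np.ndarray, enc_seq: np.ndarray) -> float:
    """Best gapless profile/sequence segment score by full enumeration of
    every (profile start, sequence start, length) placement."""
    L = profile_scores.shape[0]
    S = len(enc_seq)
    best = 0.0
    for i0 in range(L):
        for j0 in range(S):
            total = 0.0
            for t in range(min(L - i0, S - j0)):
                aa = enc_seq[j0 + t]
                total += 0.0 if aa == 20 else profile_scores[i0 + t, aa]
                if total > best:
                    best = total
    return best
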