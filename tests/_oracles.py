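"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept separate from the package code
paths they verify: distances by Floyd–Warshall, shortest-path counts by
minimal-length walk counting (powers of the adjacency matrix), cliques by
subset enumeration, components by union-find, hypergeometric tails by
binomial-coefficient summation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def adjacency(g, nodes):
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=np.int64)
    for u, v in g.edges():
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1
    return A


def floyd_warshall(A):
    n = len(A)
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k][:, None] + D[k, :][None, :])
    return D


def path_counts(A, D):
    """sigma[s, t] = number of shortest s-t paths, via walks of minimal
    length (a walk of length d(s,t) cannot revisit a vertex)."""
    n = len(A)
    diam = int(np.max(D[np.isfinite(D)]))
    S = np.zeros((n, n))
    P = np.eye(n, dtype=object)
    M = np.eye(n, dtype=np.int64)
    for d in range(diam + 1):
        S[D == d] = M[D == d]
        M = M @ A
    return S


def betweenness(A):
    D = floyd_warshall(A)
    S = path_counts(A, D)
    n = len(A)
    out = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or S[s, t] == 0:
                    continue
                if D[s, v] + D[v, t] == D[s, t]:
                    out[v] += S[s, v] * S[v, t] / S[s, t]
    return out


def stress(A):
    D = floyd_warshall(A)
    S = path_counts(A, D)
    n = len(A)
    out = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t):
                    continue
                if D[s, v] + D[v, t] == D[s, t]:
                    out[v] += S[s, v] * S[v, t]
    return out


def closeness(A):
    D = floyd_warshall(A)
    return (len(A) - 1) / D.sum(axis=1)


def eccentricity_inv(A):
    D = floyd_warshall(A)
    return 1.0 / D.max(axis=1)


def radiality(A):
    D = floyd_warshall(A)
    diam = D.max()
    n = len(A)
    return np.array(
        [sum(diam + 1 - D[v, w] for w in range(n) if w != v) / (n - 1)
         for v in range(n)]
    )


def clustering(A):
    n = len(A)
    out = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(A[v])
        d = len(nb)
        if d < 2:
            continue
        e = sum(A[a, b] for a, b in itertools.combinations(nb, 2))
        out[v] = 2.0 * e / (d * (d - 1))
    return out


def _components(A, members):
    members = list(members)
    parent = {v: v for v in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(members, 2):
        if A[a, b]:
            parent[find(a)] = find(b)
    comps: dict = {}
    for v in members:
        comps.setdefault(find(v), []).append(v)
    return list(comps.values())


def mnc_dmnc(A, eps=1.7):
    n = len(A)
    mnc, dmnc = np.zeros(n), np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(A[v])
        if len(nb) == 0:
            continue
        comps = _components(A, nb)
        comp = max(comps, key=lambda c: (len(c), sorted(c)))
        e = sum(A[a, b] for a, b in itertools.combinations(comp, 2))
        mnc[v] = len(comp)
        dmnc[v] = e / len(comp) ** eps
    return mnc, dmnc


def mcc(A):
    """Sum over maximal cliques containing v of (|C|-1)!, by subset
    enumeration (feasible for n <= ~12)."""
    n = len(A)
    nodes = list(range(n))
    out = np.zeros(n)
    for r in range(1, n + 1):
        for sub in itertools.combinations(nodes, r):
            if any(not A[a, b] for a, b in itertools.combinations(sub, 2)):
                continue
            s = set(sub)
            maximal = all(
                any(not A[w, u] for u in sub) for w in nodes if w not in s
            )
            if maximal:
                for v in sub:
                    out[v] += math.factorial(r - 1)
    return out


def epc_exact(A):
    """Exact expected component size of v over all edge subsets at keep
    probability 1/2 (feasible for few edges)."""
    n = len(A)
    edges = [(a, b) for a, b in itertools.combinations(range(n), 2) if A[a, b]]
    total = np.zeros(n)
    for mask in range(2 ** len(edges)):
        B = np.zeros_like(A)
        for i, (a, b) in enumerate(edges):
            if mask >> i & 1:
                B[a, b] = B[b, a] = 1
        for comp in _components(B, range(n)):
            for v in comp:
                total[v] += len(comp)
    return total / 2 ** len(edges)


def bottleneck(g, nodes):
    """Independent re-derivation of the BFS-tree bottleneck score with the
    declared first-discovered-parent / sorted-neighbour tie rule."""
    n = len(nodes)
    score = {v: 0 for v in nodes}
    for s in nodes:
        children: dict = {v: [] for v in nodes}
        seen = {s}
        queue = [s]
        while queue:
            u = queue.pop(0)
            for w in sorted(g[u]):
                if w not in seen:
                    seen.add(w)
                    children[u].append(w)
                    queue.append(w)

        def count(v):
            return sum(1 + count(c) for c in children[v])

        for v in seen:
            if count(v) > n / 4.0:
                score[v] += 1
    return score


def hypergeom_tail(N, K, n, kmin):
    """P(X >= kmin) for X ~ Hypergeom(N, K, n), by direct summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(max(kmin, max(0, n - (N - K))), min(K, n) + 1)
    ) / total


def median_rank_exact_p(obs_median, m, k):
    """Exact P(median of k iid uniform ranks on 1..m <= obs) by full
    enumeration of the m^k rank vectors."""
    hits = 0
    for combo in itertools.product(range(1, m + 1), repeat=k):
        if float(np.median(combo)) <= obs_median:
            hits += 1
    return hits / m**k
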