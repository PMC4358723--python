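"""Independent reference implementations used only as test oracles.

Each oracle is coded from the mathematical definition, in a deliberately
different style from the package (plain Python loops, no numpy linear
algebra), so agreement is evidence of correctness rather than shared
bugs.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# brute-force dense MCL (loop-based)


def brute_mcl(
    nodes: list[str],
    edges: dict[tuple[str, str], float],
    inflation: float = 15.0,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[set[str]]:
    """Markov clustering by direct iteration on a list-of-lists matrix."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for (a, b), w in edges.items():
        i, j = idx[a], idx[b]
        m[i][j] = w
        m[j][i] = w
    for i in range(n):
        incident = max(m[i]) if any(m[i]) else 1.0
        m[i][i] = incident

    def col_normalize(mat):
        out = [row[:] for row in mat]
        for j in range(n):
            s = sum(out[i][j] for i in range(n))
            if s > 0:
                for i in range(n):
                    out[i][j] /= s
        return out

    m = col_normalize(m)
    for _ in range(max_iter):
        prev = m
        # expansion: matrix square
        sq = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for k in range(n):
                if m[i][k]:
                    for j in range(n):
                        sq[i][j] += m[i][k] * m[k][j]
        # inflation then renormalize, prune, renormalize
        infl = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        infl = col_normalize(infl)
        for i in range(n):
            for j in range(n):
                if infl[i][j] < prune:
                    infl[i][j] = 0.0
        m = col_normalize(infl)
        diff = max(
            abs(m[i][j] - prev[i][j]) for i in range(n) for j in range(n)
        )
        if diff < tol:
            break

    # clusters: connected components of the symmetrized support
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if m[i][j] > prune or m[j][i] > prune:
                adj[i].add(j)
                adj[j].add(i)
    seen = [False] * n
    clusters = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], set()
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.add(nodes[u])
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(comp)
    return clusters


# ---------------------------------------------------------------------------
# monophyly by explicit edge enumeration on binary trees


def newick_edge_bipartitions(adjacency: dict[int, set[int]], leaves: dict[int, str]):
    """All bipartitions (as frozensets of tip labels) from removing one edge."""
    sides = []
    for u in adjacency:
        for v in adjacency[u]:
            if u >= v:
                continue
            stack, seen, tips = [v], {u, v}, set()
            while stack:
                x = stack.pop()
                if x in leaves:
                    tips.add(leaves[x])
                for y in adjacency[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            sides.append(frozenset(tips))
    return sides


def monophyletic_by_edges(
    adjacency: dict[int, set[int]], leaves: dict[int, str], tipset: set[str]
) -> bool:
    all_tips = set(leaves.values())
    if len(tipset) == 1 or tipset == all_tips:
        return True
    target = frozenset(tipset)
    comp = frozenset(all_tips - tipset)
    for side in newick_edge_bipartitions(adjacency, leaves):
        if side == target or side == comp:
            return True
    return False


# ---------------------------------------------------------------------------
# exact hypergeometric and Pearson chi-squared


def exact_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by summing the exact factorial formula."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


def pearson_chi2(table) -> float:
    """Sum over cells of (O - E)^2 / E with margin-derived expectations."""
    r = [sum(row) for row in table]
    c = [sum(table[i][j] for i in range(len(table))) for j in range(len(table[0]))]
    n = sum(r)
    stat = 0.0
    for i in range(len(table)):
        for j in range(len(table[0])):
            e = r[i] * c[j] / n
            stat += (table[i][j] - e) ** 2 / e
    return stat


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, by hand


def bh_adjust(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# random binary unrooted trees (for monophyly property tests)


def random_unrooted_tree(tips: list[str], rng) -> str:
    """Random binary unrooted newick by sequential tip insertion."""
    assert len(tips) >= 3

    def build(group):
        if len(group) == 1:
            return group[0]
        if len(group) == 2:
            return f"({group[0]},{group[1]})"
        k = 1 + int(rng.integers(len(group) - 1))
        members = list(group)
        rng.shuffle(members)
        return f"({build(members[:k])},{build(members[k:])})"

    members = list(tips)
    rng.shuffle(members)
    k = 1 + int(rng.integers(len(members) - 2))
    j = k + 1 + int(rng.integers(len(members) - k - 1))
    a, b, c = members[:k], members[k:j], members[j:]
    return f"({build(a)},{build(b)},{build(c)});"
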