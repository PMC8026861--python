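"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the defining formulas or as an
exhaustive enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------- meta ----

def fixed_pooled(thetas, variances):
    w = [1.0 / v for v in variances]
    return sum(wi * ti for wi, ti in zip(w, thetas)) / sum(w)


def cochran_q_oracle(thetas, variances):
    mu = fixed_pooled(thetas, variances)
    return sum((t - mu) ** 2 / v for t, v in zip(thetas, variances))


def dl_tau2_oracle(thetas, variances):
    k = len(thetas)
    q = cochran_q_oracle(thetas, variances)
    w = [1.0 / v for v in variances]
    c = sum(w) - sum(wi * wi for wi in w) / sum(w)
    return max(0.0, (q - (k - 1)) / c)


def pool_oracle(thetas, variances):
    """(pooled, se, model) by the Q<=df fixed / else DL-random rule."""
    k = len(thetas)
    q = cochran_q_oracle(thetas, variances)
    if q <= k - 1:
        model, w = "fixed", [1.0 / v for v in variances]
    else:
        tau2 = dl_tau2_oracle(thetas, variances)
        model, w = "random", [1.0 / (v + tau2) for v in variances]
    pooled = sum(wi * ti for wi, ti in zip(w, thetas)) / sum(w)
    se = sum(w) ** -0.5
    return pooled, se, model


# --------------------------------------------------------------- enrich ----

def hypergeom_tail_oracle(overlap, n_bg, set_size, query_size):
    """P(X >= overlap) by direct PMF summation, X ~ Hypergeom(n_bg, set_size, query_size)."""
    hi = min(set_size, query_size)
    total = 0.0
    for x in range(overlap, hi + 1):
        total += (
            math.comb(set_size, x)
            * math.comb(n_bg - set_size, query_size - x)
            / math.comb(n_bg, query_size)
        )
    return min(total, 1.0)


def bh_stepup_oracle(pvals):
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


# ---------------------------------------------------------------- paths ----

def all_min_paths_dfs(edges, source, target):
    """Every minimum-hop simple directed path, by exhaustive DFS.

    ``edges``: iterable of (u, v).  Returns a sorted list of node tuples.
    """
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    found: list[tuple[str, ...]] = []
    best = [math.inf]

    def dfs(node, path):
        if len(path) - 1 > best[0]:
            return
        if node == target:
            if len(path) - 1 < best[0]:
                best[0] = len(path) - 1
                found.clear()
            if len(path) - 1 == best[0]:
                found.append(tuple(path))
            return
        for nxt in adj.get(node, []):
            if nxt not in path:
                dfs(nxt, path + [nxt])

    dfs(source, [source])
    return sorted(found)


# ------------------------------------------------------------ relations ----

def protective_membership_oracle(rows, disease_a, disease_b):
    """Exhaustive double-loop scan for the two cross-disease sign motifs.

    ``rows``: iterable of (subject, object, sign) with sign in {+1, -1},
    assumed already aggregated (one row per ordered pair).  Returns the
    two gene sets (inhibited promoters, activated inhibitors).
    """
    inhibited, activated = set(), set()
    genes = {o for s, o, _ in rows if s == disease_a} | {
        s for s, o, _ in rows if o == disease_b
    }
    for g in genes:
        for s1, o1, sign1 in rows:
            if (s1, o1) != (disease_a, g):
                continue
            for s2, o2, sign2 in rows:
                if (s2, o2) != (g, disease_b):
                    continue
                if sign1 == -1 and sign2 == +1:
                    inhibited.add(g)
                if sign1 == +1 and sign2 == -1:
                    activated.add(g)
    return inhibited, activated
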