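"""Independent brute-force oracles the implementation is checked against."""

from itertools import combinations

import numpy as np


def mwu_exact(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of assignments.

    Enumerates every way of labelling the pooled values, computes the
    exact null distribution of U, and returns (U_observed, p) with the
    two-sided p defined as ``2 * min(P(U <= u), P(U >= u))`` capped at 1.
    Assumes no ties.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])

    def u_stat(a, b):
        return sum(1.0 for xi in a for yj in b if xi > yj)

    u_obs = u_stat(x, y)
    dist = []
    idx = range(n1 + n2)
    for comb in combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(comb)] = True
        dist.append(u_stat(pooled[mask], pooled[~mask]))
    dist = np.asarray(dist)
    p_le = (dist <= u_obs).mean()
    p_ge = (dist >= u_obs).mean()
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def bh_stepup(p):
    """Reference Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def evc_dense(adjacency):
    """Eigenvector centrality from a dense symmetric eigendecomposition.

    Returns the nonnegative unit-norm leading eigenvector restricted to
    the largest connected component (zeros elsewhere).
    """
    A = np.asarray(adjacency, float)
    n = A.shape[0]
    # connected components by BFS
    seen = np.zeros(n, dtype=bool)
    components = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.where(A[v] > 0)[0]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        components.append(sorted(comp))
    comp = max(components, key=lambda c: (len(c), -min(c)))
    sub = A[np.ix_(comp, comp)]
    vals, vecs = np.linalg.eigh(sub)
    lead = np.abs(vecs[:, np.argmax(vals)])
    lead /= np.linalg.norm(lead)
    out = np.zeros(n)
    out[comp] = lead
    return out
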