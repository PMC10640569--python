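"""Batched union-find kernel for attack traces.

Traces are computed in reverse: nodes are re-inserted from the fully
removed state, merging components with union-find, which makes one full
N-step trace cost O(N^2 + E alpha) instead of recomputing components on
each induced subgraph.  The public, pure-Python ``component_trace`` in
``attack`` implements the same algorithm and is the tested reference; this
kernel exists so that 100-iteration sweeps over dense density grids stay
within desk budgets.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _find(parent: np.ndarray, x: int) -> int:
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:  # path compression
        parent[x], x = root, parent[x]
    return root


@njit(cache=False)
def batch_attack(
    indptr: np.ndarray, indices: np.ndarray, orders: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Percolation point and pre-failure counts for a batch of removal orders.

    Returns ``(perc, prefail_counts)``: ``perc[r]`` is the first-peak
    fraction k*/N of the second-largest-component trace for order ``r``;
    ``prefail_counts[v]`` counts the iterations in which node ``v`` was
    removed strictly before the percolation step.
    """
    n_iter, n = orders.shape
    perc = np.empty(n_iter)
    prefail = np.zeros(n, dtype=np.int64)
    for r in range(n_iter):
        order = orders[r]
        parent = np.full(n, -1, dtype=np.int64)
        size = np.zeros(n, dtype=np.int64)
        s2 = np.zeros(n + 1, dtype=np.int64)  # s2[k]: after removing first k nodes
        for k in range(n - 1, 0, -1):
            v = order[k]
            parent[v] = v
            size[v] = 1
            for e in range(indptr[v], indptr[v + 1]):
                u = indices[e]
                if parent[u] != -1:
                    ru = _find(parent, u)
                    rv = _find(parent, v)
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
            m1 = 0
            m2 = 0
            for x in range(n):
                if parent[x] == x:
                    s = size[x]
                    if s > m1:
                        m2 = m1
                        m1 = s
                    elif s > m2:
                        m2 = s
            s2[k] = m2
        best = np.int64(-1)
        kstar = 1
        for k in range(1, n + 1):
            if s2[k] > best:
                best = s2[k]
                kstar = k
        perc[r] = kstar / n
        for k in range(kstar - 1):
            prefail[order[k]] += 1
    return perc, prefail
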