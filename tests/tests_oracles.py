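"""Independent brute-force oracles shared by the acceptance tests."""

import numpy as np


def brute_force_degree_fast(series: np.ndarray, r_threshold: float = 0.25) -> np.ndarray:
    """Degree oracle via the explicit full correlation matrix (np.corrcoef)."""
    r = np.corrcoef(series, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return (r > r_threshold).sum(axis=1)


def union_find(edges, n_nodes):
    """Connected components of an undirected edge list, as sorted edge sets."""
    parent = list(range(n_nodes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    groups = {}
    for i, j in edges:
        groups.setdefault(find(i), set()).add(tuple(sorted((i, j))))
    return sorted(sorted(g) for g in groups.values())
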