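"""Independent brute-force oracles used to check the implementation."""

import itertools

import numpy as np


def all_partitions(items):
    """Every partition of a list, by recursive insertion."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1:]
        yield part + [[first]]


def best_valid_partition_objective(s_matrix, sessions):
    """Exhaustive optimum of the clustering objective (sum over clusters of
    mean pairwise similarity, singletons contribute 0) over all partitions
    with session-disjoint clusters."""
    best = -np.inf
    for part in all_partitions(list(range(len(sessions)))):
        if not all(len({sessions[m] for m in c}) == len(c) for c in part):
            continue
        obj = 0.0
        for c in part:
            if len(c) >= 2:
                pairs = list(itertools.combinations(c, 2))
                obj += sum(s_matrix[i, j] for i, j in pairs) / len(pairs)
        best = max(best, obj)
    return best


def bfs_components(adjacency):
    """Connected components of a boolean adjacency matrix by breadth-first
    search."""
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            node = queue.pop(0)
            comp.append(node)
            for nxt in np.flatnonzero(adjacency[node]):
                if not seen[nxt]:
                    seen[nxt] = True
                    queue.append(int(nxt))
        comps.append(sorted(comp))
    return comps


def js_direct(p, q):
    """Jensen-Shannon divergence (bits) by direct summation."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    total = 0.0
    for a, b in ((p, m), (q, m)):
        for ai, bi in zip(a, b):
            if ai > 0:
                total += 0.5 * ai * np.log2(ai / bi)
    return total


def random_small_component(rng, n_sessions=3, max_per_session=2,
                           edge_prob=0.6, sim_range=(0.3, 1.0)):
    """Random similarity matrix + session labels for a tiny component."""
    sizes = rng.integers(0, max_per_session + 1, size=n_sessions)
    while sizes.sum() < 2:
        sizes = rng.integers(0, max_per_session + 1, size=n_sessions)
    n = int(sizes.sum())
    sessions = np.repeat(np.arange(n_sessions), sizes)
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if sessions[i] != sessions[j] and rng.random() < edge_prob:
                s[i, j] = s[j, i] = rng.uniform(*sim_range)
    return s, sessions
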