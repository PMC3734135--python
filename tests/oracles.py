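"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (loops, BFS with a deque, explicit
sums of squares) kept separate from the package code paths they check.
"""

from collections import deque

import numpy as np


def pearson_pairwise(x):
    """Textbook Pearson r for every column pair of a (t, n) array."""
    t, n = x.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = x[:, i], x[:, j]
            num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
            den = np.sqrt(np.sum((xi - xi.mean()) ** 2)
                          * np.sum((xj - xj.mean()) ** 2))
            out[i, j] = out[j, i] = num / den if den > 0 else 0.0
    return out


def bfs_distances(adj, source):
    """Unweighted shortest-path distances from source; inf if unreachable."""
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in np.flatnonzero(adj[u]):
            if dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def nodal_global_efficiency(adj):
    """Per-node mean inverse BFS distance; unreachable pairs contribute 0."""
    n = adj.shape[0]
    out = np.zeros(n)
    if n < 2:
        return out
    for i in range(n):
        d = bfs_distances(adj, i)
        inv = np.zeros(n)
        finite = np.isfinite(d) & (d > 0)
        inv[finite] = 1.0 / d[finite]
        out[i] = inv.sum() / (n - 1)
    return out


def network_efficiency(adj):
    return float(nodal_global_efficiency(adj).mean()) if adj.shape[0] else 0.0


def nodal_local_efficiency(adj):
    """Global efficiency of each node's neighbor-induced subgraph."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        out[i] = network_efficiency(adj[np.ix_(nb, nb)])
    return out


def clustering_by_triples(adj):
    """Clustering coefficient by explicit neighbor-pair enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        links = 0
        for a in range(nb.size):
            for b in range(a + 1, nb.size):
                if adj[nb[a], nb[b]]:
                    links += 1
        out[i] = 2.0 * links / (nb.size * (nb.size - 1))
    return out


def anova_2way_within(y):
    """Cell-means sums-of-squares oracle for y[subject, condition, session].

    Returns dict of (ss_effect, ss_error, df_num, df_den, F,
    partial_eta_squared) per effect, computed with explicit loops.
    """
    y = np.asarray(y, float)
    n, a, b = y.shape
    m = y.mean()
    ms = y.mean(axis=(1, 2))
    mc = y.mean(axis=(0, 2))
    mb = y.mean(axis=(0, 1))
    ss_total = sum((y[s, c, t] - m) ** 2
                   for s in range(n) for c in range(a) for t in range(b))
    ss_subj = a * b * sum((ms[s] - m) ** 2 for s in range(n))
    ss_cond = n * b * sum((mc[c] - m) ** 2 for c in range(a))
    ss_sess = n * a * sum((mb[t] - m) ** 2 for t in range(b))
    ss_cb = n * sum((y[:, c, t].mean() - mc[c] - mb[t] + m) ** 2
                    for c in range(a) for t in range(b))
    ss_cond_err = b * sum((y[s, c].mean() - ms[s] - mc[c] + m) ** 2
                          for s in range(n) for c in range(a))
    ss_sess_err = a * sum((y[s, :, t].mean() - ms[s] - mb[t] + m) ** 2
                          for s in range(n) for t in range(b))
    ss_cb_err = (ss_total - ss_subj - ss_cond - ss_sess - ss_cb
                 - ss_cond_err - ss_sess_err)

    def pack(ss_eff, ss_err, dfn, dfd):
        F = (ss_eff / dfn) / (ss_err / dfd) if ss_err > 0 else np.nan
        peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else np.nan
        return dict(ss_effect=ss_eff, ss_error=ss_err, df_num=dfn,
                    df_den=dfd, F=F, partial_eta_squared=peta)

    return {
        "condition": pack(ss_cond, ss_cond_err, a - 1, (a - 1) * (n - 1)),
        "session": pack(ss_sess, ss_sess_err, b - 1, (b - 1) * (n - 1)),
        "condition x session": pack(ss_cb, ss_cb_err, (a - 1) * (b - 1),
                                    (a - 1) * (b - 1) * (n - 1)),
        "total": ss_total,
        "subject": ss_subj,
    }
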