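"""Independent reference implementations used only to check the package.

These are deliberately written from scratch (no calls into proxnet, no
scipy clustering) so that each dual-route test compares two genuinely
different code paths.
"""

import numpy as np


def oracle_cophenetic(consensus):
    """Average-linkage agglomeration + cophenetic distances by explicit
    cluster-merge bookkeeping; Pearson correlation at the end."""
    consensus = np.asarray(consensus, dtype=float)
    n = consensus.shape[0]
    D = 1.0 - consensus
    clusters = {i: [i] for i in range(n)}
    dist = {(a, b): D[a, b] for a in range(n) for b in range(a + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new_dists = {}
        for c, members in clusters.items():
            # unweighted average linkage over original-point pairs
            total = sum(D[i, j] for i in merged for j in members)
            new_dists[c] = total / (len(merged) * len(members))
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, d in new_dists.items():
            key = (min(c, next_id), max(c, next_id))
            dist[key] = d
        clusters[next_id] = merged
        next_id += 1
    iu = np.triu_indices(n, 1)
    x, y = D[iu], coph[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def oracle_principal_eigenvector(A):
    """Max-normalized principal eigenvector via dense eigendecomposition."""
    w, v = np.linalg.eigh(np.asarray(A, dtype=float))
    x = np.abs(v[:, -1])
    return x / x.max()


def random_symmetric_consensus(n, rng):
    M = rng.uniform(0, 1, size=(n, n))
    C = (M + M.T) / 2
    np.fill_diagonal(C, 1.0)
    return C
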