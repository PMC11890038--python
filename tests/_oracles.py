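"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and window-by-window so it shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def brute_count(sequences, k: int, min_count: int = 1) -> dict[str, int]:
    """Window-by-window canonical k-mer counter."""
    if isinstance(sequences, str):
        sequences = [sequences]
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            rc = w.translate(_COMP)[::-1]
            canon = w if w <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1
    return {kmer: c for kmer, c in counts.items() if c >= min_count}


def eig_pca(values: np.ndarray, n_components: int):
    """PCA via explicit eigendecomposition of the sample covariance."""
    x = np.asarray(values, float)
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    evr = evals / evals.sum()
    loadings = evecs[:, :n_components].T
    scores = centered @ loadings.T
    return scores, loadings, evr[:n_components]


def lloyd_inertia(points: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, float]:
    """Run Lloyd iterations to a fixed point from given centers."""
    points = np.asarray(points, float)
    centers = np.asarray(centers, float).copy()
    labels = np.zeros(len(points), dtype=int)
    for _ in range(200):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new = np.array(
            [
                points[labels == j].mean(axis=0) if np.any(labels == j) else centers[j]
                for j in range(len(centers))
            ]
        )
        if np.allclose(new, centers, atol=1e-12):
            break
        centers = new
    inertia = float(((points - centers[labels]) ** 2).sum())
    return labels, inertia


def exact_jaccard(seq_a, seq_b, k: int, min_count: int = 1) -> float:
    """Jaccard of the full canonical k-mer sets (no sketching)."""
    sa = set(brute_count(seq_a, k, min_count))
    sb = set(brute_count(seq_b, k, min_count))
    if not sa | sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with uniform branch lengths.

    Returns (leaf names, pairwise path-length matrix).  Built by attaching
    each new leaf to a uniformly chosen existing edge; distances computed
    by breadth-first search over the explicit graph.
    """
    # graph: adjacency dict node -> {neighbor: weight}; leaves are "L0".."Ln-1"
    def add_edge(g, a, b, w):
        g.setdefault(a, {})[b] = w
        g.setdefault(b, {})[a] = w

    def drop_edge(g, a, b):
        del g[a][b]
        del g[b][a]

    g: dict = {}
    internal = 0
    blen = lambda: float(rng.uniform(0.1, 1.0))
    add_edge(g, "L0", "I0", blen())
    add_edge(g, "L1", "I0", blen())
    add_edge(g, "L2", "I0", blen())
    internal = 1
    for i in range(3, n_leaves):
        edges = [(a, b) for a in g for b in g[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = g[a][b]
        mid = f"I{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8))
        drop_edge(g, a, b)
        add_edge(g, a, mid, w * split)
        add_edge(g, b, mid, w * (1 - split))
        add_edge(g, f"L{i}", mid, blen())
    names = [f"L{i}" for i in range(n_leaves)]
    dist = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(names):
        seen = {src: 0.0}
        frontier = [src]
        while frontier:
            nxt = []
            for node in frontier:
                for nb, w in g[node].items():
                    if nb not in seen:
                        seen[nb] = seen[node] + w
                        nxt.append(nb)
            frontier = nxt
        for j, dst in enumerate(names):
            dist[i, j] = seen[dst]
    dist = (dist + dist.T) / 2  # exact symmetry despite float summation order
    np.fill_diagonal(dist, 0.0)
    return names, dist
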