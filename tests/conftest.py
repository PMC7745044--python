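import numpy as np
import pytest

from semifc.coherence import FCMatrix


def fig1_triangle() -> FCMatrix:
    """Three-node network whose distances are 2 (A-B), 4 (B-C) and 7 (A-C):
    the direct A-C edge is longer than the two-hop route (6), so exactly
    that edge is semi-metric with ratio 7/6."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1 / 3  # l = 2
    w[1, 2] = w[2, 1] = 1 / 5  # l = 4
    w[0, 2] = w[2, 0] = 1 / 8  # l = 7
    return FCMatrix(w, ["A", "B", "C"])


@pytest.fixture
def triangle() -> FCMatrix:
    return fig1_triangle()


def random_complete_fc(rng: np.random.Generator, n: int) -> FCMatrix:
    """Complete weighted graph with coherence weights U(0.05, 1)."""
    u = rng.uniform(0.05, 1.0, size=(n, n))
    w = np.triu(u, 1)
    w = w + w.T
    return FCMatrix(w, [f"n{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive implementations)

def floyd_warshall_oracle(lengths: np.ndarray) -> np.ndarray:
    d = lengths.astype(float).copy()
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def enumerate_paths_oracle(lengths: np.ndarray, i: int, j: int) -> float:
    """Shortest i-j distance by exhaustive simple-path enumeration."""
    n = lengths.shape[0]
    best = [np.inf]

    def visit(node, used, acc):
        if acc >= best[0]:
            return
        if node == j:
            best[0] = acc
            return
        for nxt in range(n):
            if nxt not in used:
                visit(nxt, used | {nxt}, acc + lengths[node, nxt])

    visit(i, {i}, 0.0)
    return best[0]


def triple_loop_clustering_oracle(w: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering via explicit triangle loops."""
    n = w.shape[0]
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (w[i, j] / wmax * w[i, h] / wmax * w[j, h] / wmax) ** (1 / 3)
        out[i] = s / (k * (k - 1))
    return out
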