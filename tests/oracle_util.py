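"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: the
multilayer modularity evaluator is a literal quadruple loop over
(node i, node j, layer s, layer r), and the partition enumerator yields
every set partition via restricted growth strings.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


def eq1_modularity(
    layers: np.ndarray, labels: np.ndarray, gamma: float, omega: float
) -> float:
    """Literal evaluation of the multilayer quality function.

    Intra-layer term (A_ijs - gamma k_is k_js / 2m_s) for every ordered pair
    including i = j; ordinal coupling omega between copies of the same node
    in adjacent layers; normalization 2mu = sum of strengths plus twice the
    total coupling weight.
    """
    T, N, _ = layers.shape
    k = layers.sum(axis=2)
    two_m = k.sum(axis=1)
    total = 0.0
    for s in range(T):
        for r in range(T):
            for i in range(N):
                for j in range(N):
                    if s == r and labels[s, i] == labels[r, j]:
                        total += layers[s, i, j] - gamma * k[s, i] * k[s, j] / two_m[s]
                    if i == j and abs(s - r) == 1 and labels[s, i] == labels[r, j]:
                        total += omega
    two_mu = two_m.sum() + 2.0 * omega * N * (T - 1)
    return total / two_mu


def set_partitions(n: int) -> Iterator[np.ndarray]:
    """All set partitions of n elements as restricted growth label vectors."""
    labels = np.zeros(n, dtype=int)

    def rec(pos: int, max_label: int):
        if pos == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[pos] = lab
            yield from rec(pos + 1, max(max_label, lab))

    yield from rec(1, 0)


def exhaustive_max_q(
    layers: np.ndarray, gamma: float, omega: float
) -> tuple[float, np.ndarray]:
    """Exhaustive search of the quality function over all partitions of the
    node-layer copies (feasible only for a handful of copies)."""
    T, N, _ = layers.shape
    best_q, best_labels = -np.inf, None
    for flat in set_partitions(T * N):
        lab = flat.reshape(T, N)
        q = eq1_modularity(layers, lab, gamma, omega)
        if q > best_q:
            best_q, best_labels = q, lab
    return best_q, best_labels


def random_multilayer(
    rng: np.random.Generator, n_nodes: int, n_layers: int
) -> np.ndarray:
    """Random non-negative symmetric layer stack with no all-zero layer."""
    while True:
        layers = np.zeros((n_layers, n_nodes, n_nodes))
        for s in range(n_layers):
            w = rng.uniform(0, 1, size=(n_nodes, n_nodes))
            mask = rng.random((n_nodes, n_nodes)) < 0.7
            w = np.triu(w * mask, k=1)
            layers[s] = w + w.T
        if np.all(layers.sum(axis=(1, 2)) > 0):
            return layers
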