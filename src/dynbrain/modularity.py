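"""Multilayer modularity and a generalized (temporal) Louvain optimizer.

The quality function is the multilayer modularity

    Q(gamma, omega) = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma * k_is k_js / 2m_s) * delta(s, r)
                                             + delta(i, j) * omega_jrs ] * delta(M_is, M_jr)

where ``A_ijs`` is the (non-negative) connectivity between nodes i and j in
layer s, ``k_is = sum_j A_ijs`` the intra-layer strength, ``2m_s`` the layer
total, gamma the topological resolution and omega the inter-layer coupling.
Coupling is *ordinal*: ``omega_jrs = omega`` between copies of the same node
in adjacent layers (|r - s| = 1), zero otherwise — the established temporal
convention for this quality function.  The normalization ``2mu`` counts every
copy's total strength including its coupling strength:

    2mu = sum_{js} k_js + 2 * omega * n_nodes * (n_layers - 1)

so Q values are comparable across omega.  The sum runs over ordered pairs and
includes the ``i = j`` intra-layer diagonal null term, so a single-layer
two-clique graph at gamma = 1 with the two cliques as modules scores Q = 1/2.

Optimization is a generalized Louvain heuristic: a greedy phase sweeps
node-layer copies in seeded random order, moving each copy to the module
with maximal positive modularity gain (candidates include a fresh singleton
module); when no move improves, modules are contracted into supernodes of a
reduced modularity matrix and the greedy phase repeats, until a whole level
yields no gain above 1e-10.  Negative connectivity entries are zeroed before
optimization (the Newman–Girvan null is ill-behaved on signed weights); a
signed variant is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .windows import DynamicGraph

#: A move is accepted only if it increases Q by more than this.
MOVE_TOL = 1e-10

#: Hard cap on greedy sweeps per level before flagging pathological input.
MAX_SWEEPS = 100


@dataclass(frozen=True)
class ModularityParams:
    """Resolution gamma (> 0), ordinal coupling omega (>= 0), ensemble size, seed."""

    gamma: float = 1.0
    omega: float = 1.0
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")


@dataclass(frozen=True)
class MultilayerGraph:
    """Non-negative layer stack with precomputed strengths and totals."""

    layers: np.ndarray           # (T, N, N), entries >= 0, zero diagonal
    strengths: np.ndarray        # k_is, shape (T, N)
    layer_totals: np.ndarray     # 2m_s per layer, shape (T,)
    two_mu: float                # 2mu including coupling contribution
    gamma: float
    omega: float

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


@dataclass(frozen=True)
class Partition:
    """Module labels per node per layer (``labels[s, i]``, positive ints) and Q."""

    labels: np.ndarray
    q: float


@dataclass(frozen=True)
class PartitionEnsemble:
    partitions: tuple[Partition, ...]
    params: ModularityParams

    @property
    def n_runs(self) -> int:
        return len(self.partitions)

    @property
    def best(self) -> Partition:
        return max(self.partitions, key=lambda p: p.q)


def build_multilayer(
    dg: DynamicGraph | np.ndarray, params: ModularityParams
) -> MultilayerGraph:
    """Assemble the multilayer structure from a dynamic graph.

    Negative entries (anticorrelations) are set to zero.  A layer whose
    weights are all zero leaves the null model undefined (``m_s = 0``) and
    is a hard error.
    """
    layers = dg.layers if isinstance(dg, DynamicGraph) else np.asarray(dg, float)
    if layers.ndim != 3 or layers.shape[1] != layers.shape[2]:
        raise ValueError("layers must be a (T, N, N) stack")
    layers = np.where(layers > 0, layers, 0.0)
    for s in range(layers.shape[0]):
        np.fill_diagonal(layers[s], 0.0)
    strengths = layers.sum(axis=2)
    layer_totals = strengths.sum(axis=1)
    if np.any(layer_totals == 0):
        bad = int(np.flatnonzero(layer_totals == 0)[0]) + 1
        raise ValueError(f"layer {bad} has all-zero weights; null model undefined")
    n_layers, n_nodes = strengths.shape
    two_mu = float(layer_totals.sum()) + 2.0 * params.omega * n_nodes * max(n_layers - 1, 0)
    return MultilayerGraph(
        layers=layers,
        strengths=strengths,
        layer_totals=layer_totals,
        two_mu=two_mu,
        gamma=params.gamma,
        omega=params.omega,
    )


def modularity_q(mg: MultilayerGraph, labels: np.ndarray) -> float:
    """Exact multilayer modularity of a partition (vectorized evaluation)."""
    labels = np.asarray(labels)
    if labels.shape != (mg.n_layers, mg.n_nodes):
        raise ValueError("labels must cover the full (n_layers, n_nodes) grid")
    total = 0.0
    for s in range(mg.n_layers):
        same = labels[s][:, None] == labels[s][None, :]
        intra_w = float(mg.layers[s][same].sum())
        # sum over same-module ordered pairs (incl. i = j) of k_i k_j = sum_c K_c^2
        k = mg.strengths[s]
        mods, inv = np.unique(labels[s], return_inverse=True)
        module_k = np.bincount(inv, weights=k)
        total += intra_w - mg.gamma * float(module_k @ module_k) / mg.layer_totals[s]
    if mg.n_layers > 1:
        aligned = int((labels[:-1] == labels[1:]).sum())
        total += 2.0 * mg.omega * aligned
    return total / mg.two_mu


# ---------------------------------------------------------------------------
# Generalized Louvain
# ---------------------------------------------------------------------------

def _greedy_multilayer_phase(
    mg: MultilayerGraph,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Copy-level greedy sweeps with the implicit multilayer structure.

    Starts from ``init`` labels (default: every copy its own module) and
    returns integer labels of shape (T, N) (arbitrary ids).  Works directly
    on the layer stack so the full supra-modularity matrix is never formed.
    """
    T, N = mg.n_layers, mg.n_nodes
    if init is None:
        labels = np.arange(T * N, dtype=np.int64).reshape(T, N)
    else:
        labels = np.asarray(init, dtype=np.int64).copy()
    capacity = 2 * max(T * N, int(labels.max()) + 1) + 1
    # per-layer module strength accumulators
    mod_strength = np.zeros((T, capacity))
    for s in range(T):
        np.add.at(mod_strength[s], labels[s], mg.strengths[s])
    next_id = int(labels.max()) + 1
    gamma, omega = mg.gamma, mg.omega

    for _ in range(MAX_SWEEPS):
        moved = 0
        order = rng.permutation(T * N)
        for flat in order:
            s, i = divmod(int(flat), N)
            c = labels[s, i]
            k = mg.strengths[s, i]
            strengths_s = mod_strength[s]
            strengths_s[c] -= k  # remove copy from its module
            w = np.bincount(labels[s], weights=mg.layers[s, i], minlength=capacity)
            gains = w - (gamma * k / mg.layer_totals[s]) * strengths_s
            if omega > 0:
                if s > 0:
                    gains[labels[s - 1, i]] += omega
                if s + 1 < T:
                    gains[labels[s + 1, i]] += omega
            best = int(np.argmax(gains))  # lowest id among maximizers
            best_gain = gains[best]
            gain_c = gains[c]
            accept_tol = MOVE_TOL * mg.two_mu / 2.0
            if best_gain <= accept_tol and gain_c < -accept_tol:
                # no existing module beats a fresh singleton; split off
                if strengths_s[c] > 0:  # module c still has other members
                    d = next_id
                    next_id += 1
                    if next_id >= capacity:
                        capacity *= 2
                        mod_strength = np.pad(mod_strength, ((0, 0), (0, capacity - mod_strength.shape[1])))
                        strengths_s = mod_strength[s]
                    labels[s, i] = d
                    strengths_s[d] += k
                    moved += 1
                    continue
                strengths_s[c] += k  # already a singleton; stay
                continue
            if best != c and best_gain - gain_c > accept_tol:
                labels[s, i] = best
                strengths_s[best] += k
                moved += 1
            else:
                strengths_s[c] += k
        if moved == 0:
            return labels
    raise RuntimeError(f"greedy phase did not converge within {MAX_SWEEPS} sweeps")


def _contract(mg: MultilayerGraph, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduced modularity matrix over modules: B'_cd = sum of supra-B entries.

    Returns (B', compact_labels) where compact labels index B' rows.
    """
    _, inv = np.unique(labels, return_inverse=True)
    compact = inv.reshape(labels.shape)
    M = compact.max() + 1
    B = np.zeros((M, M))
    for s in range(mg.n_layers):
        onehot = np.zeros((mg.n_nodes, M))
        onehot[np.arange(mg.n_nodes), compact[s]] = 1.0
        W = onehot.T @ mg.layers[s] @ onehot
        K = onehot.T @ mg.strengths[s]
        B += W - mg.gamma * np.outer(K, K) / mg.layer_totals[s]
    if mg.omega > 0:
        for s in range(mg.n_layers - 1):
            np.add.at(B, (compact[s], compact[s + 1]), mg.omega)
            np.add.at(B, (compact[s + 1], compact[s]), mg.omega)
    return B, compact


def _greedy_dense_phase(
    B: np.ndarray, rng: np.random.Generator, two_mu: float
) -> np.ndarray:
    """Greedy sweeps on a dense reduced modularity matrix; returns group labels."""
    M = B.shape[0]
    groups = np.arange(M, dtype=np.int64)
    capacity = 2 * M + 1
    accept_tol = MOVE_TOL * two_mu / 2.0
    for _ in range(MAX_SWEEPS):
        moved = 0
        for x in rng.permutation(M):
            c = groups[x]
            row = B[x].copy()
            row[x] = 0.0  # the diagonal term follows x into any group
            gains = np.bincount(groups, weights=row, minlength=capacity)
            best = int(np.argmax(gains))
            gain_c = gains[c]
            if gains[best] <= accept_tol and gain_c < -accept_tol:
                others_in_c = np.any((groups == c) & (np.arange(M) != x))
                if others_in_c:
                    groups[x] = int(groups.max()) + 1
                    moved += 1
                continue
            if best != c and gains[best] - gain_c > accept_tol:
                groups[x] = best
                moved += 1
        if moved == 0:
            return groups
    raise RuntimeError(f"dense greedy phase did not converge within {MAX_SWEEPS} sweeps")


def _aggregate_levels(
    mg: MultilayerGraph, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Contract modules and optimize the reduced matrix, repeating until no
    aggregation level improves; returns copy-level labels."""
    B, compact = _contract(mg, labels)
    while True:
        groups = _greedy_dense_phase(B, rng, mg.two_mu)
        _, ginv = np.unique(groups, return_inverse=True)
        M = ginv.max() + 1
        if M == B.shape[0]:
            break
        onehot = np.zeros((B.shape[0], M))
        onehot[np.arange(B.shape[0]), ginv] = 1.0
        B = onehot.T @ B @ onehot
        compact = ginv[compact]
    return compact


def louvain_run(mg: MultilayerGraph, seed: int) -> Partition:
    """One seeded generalized-Louvain optimization; returns a local optimum.

    The greedy/aggregate cycle is iterated: after the aggregation levels
    converge, control returns to the copy level and single-copy moves are
    retried from the current partition, until a full cycle improves Q by no
    more than the move tolerance.  This refinement lets individual node-layer
    copies escape coarse modules formed during aggregation.
    """
    rng = np.random.default_rng(seed)
    labels = None
    q_prev = -np.inf
    for _ in range(MAX_SWEEPS):
        labels = _greedy_multilayer_phase(mg, rng, labels)
        labels = _aggregate_levels(mg, labels, rng)
        q = modularity_q(mg, labels)
        if q - q_prev <= MOVE_TOL:
            break
        q_prev = q
    # relabel to consecutive positive integers
    _, inv = np.unique(labels, return_inverse=True)
    final = (inv + 1).reshape(labels.shape).astype(np.int64)
    return Partition(labels=final, q=modularity_q(mg, final))


def ensemble(mg: MultilayerGraph, params: ModularityParams) -> PartitionEnsemble:
    """``n_runs`` independent seeded runs; child seeds fan out from the master seed."""
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(params.n_runs)]
    parts = tuple(louvain_run(mg, seed) for seed in seeds)
    return PartitionEnsemble(partitions=parts, params=params)
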