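"""Dynamic graph metrics from partition ensembles.

From the layer-resolved community labels of each optimization run we derive:

* **connection stability** (allegiance): for each node pair, the fraction of
  layers in which the pair shares a module, averaged over runs; symmetric
  with a unit diagonal (a node is always with itself).
* **flexibility**: ``f_i = 1 - (1/(T-1)) * sum_s delta(G_{i,s}, G_{i,s+1})``,
  the fraction of the ``T-1`` layer transitions at which node i changes
  module.
* **disjointness / cohesion**: every module change of a node at a transition
  is *cohesive* when at least one other node makes the same
  source-module -> destination-module move at that transition, and *disjoint*
  otherwise.  Disjointness is the disjoint-change count over ``T-1``;
  cohesion strength sums, over transitions, the number of partner nodes
  sharing the move, normalized by ``T-1``.  Per run and per node,
  ``flexibility * (T-1) = #disjoint + #cohesive`` by construction.

All metrics are invariant to relabeling modules within any layer and are
averaged over the ensemble's runs; no cross-run label alignment is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_io import Atlas
from .modularity import Partition, PartitionEnsemble

logger = logging.getLogger("dynbrain")


@dataclass
class MetricTable:
    """Per-node dynamic metrics of one subject (ensemble-averaged)."""

    connection_stability: np.ndarray  # (N, N), in [0, 1], diag 1
    flexibility: np.ndarray           # (N,), in [0, 1]
    disjointness: np.ndarray          # (N,), in [0, 1]
    cohesion_strength: np.ndarray     # (N,), >= 0
    disjoint_count: np.ndarray        # (N,), mean raw counts over runs
    cohesive_count: np.ndarray        # (N,)
    network_means: pd.DataFrame | None = None

    @property
    def global_disjointness(self) -> float:
        return float(self.disjointness.mean())


@dataclass(frozen=True)
class ChangeEvent:
    """One module change: node moved ``source -> dest`` at ``transition`` (0-based)."""

    transition: int
    node: int          # 0-based node index
    source: int
    dest: int
    kind: str          # "disjoint" or "cohesive"
    n_partners: int    # other nodes making the same source->dest move


def connection_stability(ens: PartitionEnsemble) -> np.ndarray:
    """Ensemble-averaged fraction of layers in which each node pair co-resides."""
    acc = None
    for part in ens.partitions:
        labels = part.labels
        T = labels.shape[0]
        same = np.zeros((labels.shape[1], labels.shape[1]))
        for s in range(T):
            same += labels[s][:, None] == labels[s][None, :]
        same /= T
        acc = same if acc is None else acc + same
    out = acc / ens.n_runs
    np.fill_diagonal(out, 1.0)
    return out


def flexibility(ens: PartitionEnsemble) -> np.ndarray:
    """Per-node fraction of transitions with a module change, run-averaged."""
    vals = []
    for part in ens.partitions:
        labels = part.labels
        if labels.shape[0] < 2:
            raise ValueError("flexibility needs at least 2 layers (T - 1 = 0)")
        changes = (labels[:-1] != labels[1:]).sum(axis=0)
        vals.append(changes / (labels.shape[0] - 1))
    return np.mean(vals, axis=0)


def change_events(partition: Partition | np.ndarray) -> list[ChangeEvent]:
    """Classify every module change of one run as disjoint or cohesive.

    A change is cohesive iff >= 1 other node moves from the same source module
    to the same destination module at the same transition.
    """
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if labels.shape[0] < 2:
        raise ValueError("change classification needs at least 2 layers")
    events: list[ChangeEvent] = []
    for t in range(labels.shape[0] - 1):
        movers = np.flatnonzero(labels[t] != labels[t + 1])
        groups: dict[tuple[int, int], list[int]] = {}
        for i in movers:
            groups.setdefault((int(labels[t, i]), int(labels[t + 1, i])), []).append(int(i))
        for (src, dst), nodes in groups.items():
            kind = "cohesive" if len(nodes) >= 2 else "disjoint"
            for i in nodes:
                events.append(ChangeEvent(t, i, src, dst, kind, len(nodes) - 1))
    return events


def change_counts(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node (disjoint count, cohesive count, partner count) for one run."""
    n_nodes = labels.shape[1]
    disjoint = np.zeros(n_nodes)
    cohesive = np.zeros(n_nodes)
    partners = np.zeros(n_nodes)
    for ev in change_events(labels):
        if ev.kind == "disjoint":
            disjoint[ev.node] += 1
        else:
            cohesive[ev.node] += 1
            partners[ev.node] += ev.n_partners
    return disjoint, cohesive, partners


def disjointness_and_cohesion(ens: PartitionEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Run-averaged per-node disjointness and cohesion strength."""
    table = compute_metrics(ens)
    return table.disjointness, table.cohesion_strength


def compute_metrics(ens: PartitionEnsemble) -> MetricTable:
    """All nodal metrics of one subject from a partition ensemble."""
    dis, coh, part, flex = [], [], [], []
    for p in ens.partitions:
        T = p.labels.shape[0]
        if T < 2:
            raise ValueError("metrics need at least 2 layers")
        d, c, np_ = change_counts(p.labels)
        dis.append(d)
        coh.append(c)
        part.append(np_)
        flex.append((d + c) / (T - 1))
    T = ens.partitions[0].labels.shape[0]
    return MetricTable(
        connection_stability=connection_stability(ens),
        flexibility=np.mean(flex, axis=0),
        disjointness=np.mean(dis, axis=0) / (T - 1),
        cohesion_strength=np.mean(part, axis=0) / (T - 1),
        disjoint_count=np.mean(dis, axis=0),
        cohesive_count=np.mean(coh, axis=0),
    )


def network_aggregate(mt: MetricTable, atlas: Atlas) -> pd.DataFrame:
    """Network-level means: nodal metrics over member nodes; stability over
    within-network node pairs (i < j).  A single-node network has no pairs;
    its stability is recorded as missing."""
    rows = []
    for net in atlas.networks:
        idx = np.asarray(net.nodes) - 1
        if len(idx) >= 2:
            sub = mt.connection_stability[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            stability = float(sub[iu].mean())
        else:
            stability = np.nan
            logger.warning("network %s has a single node; pairwise stability undefined", net.abbreviation)
        rows.append(
            {
                "network": net.abbreviation,
                "connection_stability": stability,
                "flexibility": float(mt.flexibility[idx].mean()),
                "disjointness": float(mt.disjointness[idx].mean()),
                "cohesion_strength": float(mt.cohesion_strength[idx].mean()),
            }
        )
    table = pd.DataFrame(rows).set_index("network")
    mt.network_means = table
    return table
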