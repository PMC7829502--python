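"""Sliding-window dynamic functional connectivity.

An ROI time-series matrix is cut into overlapping rectangular windows
(length and step in TR units); within each window the pairwise Pearson
correlation matrix is computed and Fisher z-transformed, giving the
ordered stack of layers of the temporal multilayer network.  With 190
volumes, a 45-TR window and a 1-TR step this produces the 146 windows
(1-45, 2-46, ..., 146-190) of the reference acquisition (TR = 2.5 s, so
a 45-TR window spans 112.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas_io import SubjectRecord

#: |r| is clipped below 1 by this margin before atanh so z stays finite.
FISHER_CLIP = 1e-7


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length and step in volumes (TR), TR in seconds."""

    length: int
    step: int = 1
    tr: float = 2.5

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("window length must be at least 3 volumes")
        if self.step < 1:
            raise ValueError("window step must be at least 1 volume")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def length_seconds(self) -> float:
        return self.length * self.tr

    @property
    def step_seconds(self) -> float:
        return self.step * self.tr


def scan_seconds(n_volumes: int, tr: float) -> float:
    """Total scan duration covered by ``n_volumes`` at repetition time ``tr``."""
    return n_volumes * tr


def n_windows(n_volumes: int, spec: WindowSpec) -> int:
    """Number of full windows: ``floor((n_volumes - length)/step) + 1``."""
    if spec.length > n_volumes:
        raise ValueError(
            f"window length {spec.length} exceeds series length {n_volumes}"
        )
    return (n_volumes - spec.length) // spec.step + 1


def window_indices(n_volumes: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """1-based inclusive (start, end) volume indices of every full window.

    Trailing volumes that do not fill a window are dropped.
    """
    count = n_windows(n_volumes, spec)
    return [
        (1 + w * spec.step, spec.length + w * spec.step) for w in range(count)
    ]


@dataclass(frozen=True)
class DynamicGraph:
    """Ordered stack of per-window Fisher-z connectivity matrices.

    ``layers`` has shape ``(T, n_nodes, n_nodes)``; each layer is symmetric
    with a zero diagonal and finite entries.  ``window_starts`` are 1-based.
    """

    layers: np.ndarray
    window_starts: tuple[int, ...]
    spec: WindowSpec

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


def dynamic_graph(subject: SubjectRecord | np.ndarray, spec: WindowSpec) -> DynamicGraph:
    """Build the dynamic graph of one subject (or raw ``nodes x volumes`` array).

    Per window: pairwise Pearson r over the window's volumes, then
    ``z = atanh(r)`` with ``|r|`` clipped to ``1 - 1e-7``; diagonal set to 0.
    A node that is constant within any window makes r undefined and is a
    hard error naming the node (1-based) and the window.
    """
    series = subject.timeseries if isinstance(subject, SubjectRecord) else np.asarray(subject, float)
    if series.ndim != 2:
        raise ValueError("time series must be a 2-D nodes x volumes array")
    n_nodes, n_volumes = series.shape
    bounds = window_indices(n_volumes, spec)
    layers = np.empty((len(bounds), n_nodes, n_nodes))
    for w, (start, end) in enumerate(bounds):
        chunk = series[:, start - 1 : end]
        sd = chunk.std(axis=1)
        if np.any(sd == 0):
            node = int(np.flatnonzero(sd == 0)[0]) + 1
            raise ValueError(
                f"node {node} is constant within window {w + 1} "
                f"(volumes {start}-{end}); correlation undefined"
            )
        r = np.corrcoef(chunk)
        np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP, out=r)
        z = np.arctanh(r)
        np.fill_diagonal(z, 0.0)
        layers[w] = (z + z.T) / 2.0  # enforce exact symmetry
    return DynamicGraph(
        layers=layers,
        window_starts=tuple(start for start, _ in bounds),
        spec=spec,
    )
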