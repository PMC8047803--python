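"""Transition network over neurons, scalar property maps, work profiles.

Pooling the consecutive-frame neuron transitions of all replicas gives an
approximate transition matrix; row-normalizing it and weighting edges by
−ln p turns shortest paths into most-probable routes (the weight sum along
a path equals −ln of the product of its transition probabilities).  Mean
pulling force per neuron localizes force peaks that are smeared out in
per-replica force–time profiles, which is how unfolding intermediates are
spotted on the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .paths import PathTrace

__all__ = [
    "TransitionGraph",
    "PropertyMap",
    "transition_matrix",
    "build_graph",
    "shortest_path_distance",
    "map_property",
    "work_profile",
]


@dataclass
class TransitionGraph:
    counts: np.ndarray  # (n_neurons, n_neurons) transition counts
    stochastic: np.ndarray  # row-normalized where the row has counts
    include_self: bool = True
    log_base: str = "e"

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def isolated(self) -> np.ndarray:
        """Neurons with no outgoing transitions (zero count rows)."""
        return np.where(self.counts.sum(axis=1) == 0)[0]


def transition_matrix(
    traces: list[PathTrace],
    n_neurons: int,
    include_self: bool = True,
) -> TransitionGraph:
    """Count neuron→neuron transitions over consecutive frames, pooled
    across all replicas, and row-normalize into transition probabilities.

    Self-transitions dominate consecutive-frame data and are counted by
    default; ``include_self=False`` drops them before normalization for a
    sparser graph.
    """
    if not traces:
        raise ValueError("no traces given")
    counts = np.zeros((n_neurons, n_neurons))
    for tr in traces:
        if tr.bmus.max() >= n_neurons:
            raise ValueError("trace contains neuron ids outside the map")
        np.add.at(counts, (tr.bmus[:-1], tr.bmus[1:]), 1.0)
    if not include_self:
        np.fill_diagonal(counts, 0.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        stochastic = np.where(row_sums > 0, counts / row_sums, 0.0)
    return TransitionGraph(counts=counts, stochastic=stochastic, include_self=include_self)


def build_graph(tg: TransitionGraph) -> nx.DiGraph:
    """Directed graph with an edge (a, b) of weight −ln p(a→b) for every
    non-zero transition probability.  Weights are non-negative, so
    self-loops never shorten a path."""
    g = nx.DiGraph(log_base="e")
    g.add_nodes_from(range(tg.n_neurons))
    rows, cols = np.nonzero(tg.stochastic)
    for a, b in zip(rows, cols):
        p = tg.stochastic[a, b]
        g.add_edge(int(a), int(b), weight=float(-np.log(p)), probability=float(p))
    return g


def shortest_path_distance(graph: nx.DiGraph, a: int, b: int) -> tuple[list[int], float]:
    """Minimal −ln-probability path from a to b.

    The returned distance equals both the sum of edge weights and
    −ln Π p along the path (asserted internally); an unreachable target
    gives an empty path and ``inf``.
    """
    if a not in graph or b not in graph:
        raise KeyError(f"unknown node in ({a}, {b})")
    if a == b:
        return [], 0.0
    try:
        path = nx.dijkstra_path(graph, a, b, weight="weight")
    except nx.NetworkXNoPath:
        return [], float("inf")
    weight_sum = sum(graph[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
    prob_prod = float(np.prod([graph[u][v]["probability"] for u, v in zip(path[:-1], path[1:])]))
    neglog = float(-np.log(prob_prod))
    assert abs(weight_sum - neglog) < 1e-9, "edge-weight sum disagrees with -ln(prod p)"
    return path, float(weight_sum)


@dataclass
class PropertyMap:
    """Per-neuron statistics of a scalar carried on trace frames; neurons
    never visited with the scalar are missing, not zero."""

    name: str
    mean: np.ndarray  # (n_neurons,), NaN where missing
    sd: np.ndarray
    count: np.ndarray  # (n_neurons,) int

    @property
    def visited(self) -> np.ndarray:
        return np.where(self.count > 0)[0]

    def argmax_neuron(self) -> int:
        """Neuron with the highest mean value (among visited neurons)."""
        masked = np.where(self.count > 0, self.mean, -np.inf)
        return int(np.argmax(masked))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "neuron": np.arange(len(self.mean)),
                f"mean_{self.name}": self.mean,
                f"sd_{self.name}": self.sd,
                "count": self.count,
            }
        ).to_csv(path, index=False)


def map_property(
    traces: list[PathTrace],
    n_neurons: int,
    scalar: str = "force",
) -> PropertyMap:
    """Average a per-frame scalar (default: pulling force) over the frames
    assigned to each neuron, pooled across replicas."""
    totals = np.zeros(n_neurons)
    sq_totals = np.zeros(n_neurons)
    counts = np.zeros(n_neurons, dtype=int)
    any_scalar = False
    for tr in traces:
        values = getattr(tr, scalar, None)
        if values is None:
            continue
        any_scalar = True
        np.add.at(totals, tr.bmus, values)
        np.add.at(sq_totals, tr.bmus, values**2)
        np.add.at(counts, tr.bmus, 1)
    if not any_scalar:
        raise ValueError(f"no trace carries the scalar {scalar!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 0, sq_totals / np.maximum(counts, 1) - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return PropertyMap(name=scalar, mean=mean, sd=sd, count=counts)


def work_profile(force: np.ndarray, extension: np.ndarray) -> np.ndarray:
    """Cumulative mechanical work W(x) = ∫ F dx (trapezoidal rule) along a
    pulling run; force in kJ mol⁻¹ nm⁻¹, extension in nm, work in
    kJ mol⁻¹.  Monotone non-decreasing whenever F ≥ 0."""
    force = np.asarray(force, dtype=float)
    extension = np.asarray(extension, dtype=float)
    if force.shape != extension.shape:
        raise ValueError("force and extension must have equal length")
    return cumulative_trapezoid(force, extension, initial=0.0)
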