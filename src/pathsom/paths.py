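"""Tracing, comparing, and clustering pathways on a trained map.

Each pulling replica becomes a route on the map — the sequence of BMUs of
its frames.  Two routes are compared frame-by-frame with

    D(A, B) = (1/n) Σ_i d(A_i, B_i)

where d(a, b) is the mean square deviation between the codebook vectors of
the two BMUs at frame i (squared feature units; no square root, matching
the definition of the pathway distance).  Average-linkage hierarchical
clustering of the pairwise D matrix then separates pathway families.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp

from .features import FeatureMatrix
from .som import SOMModel, assign_bmus

__all__ = [
    "PathTrace",
    "PathwayClustering",
    "trace_path",
    "bmu_pair_distance",
    "path_distance",
    "cluster_paths",
    "retrace",
    "linkage_to_newick",
]


@dataclass
class PathTrace:
    """Ordered BMU sequence for one replica, with per-frame distances and
    optional scalar series (force, extension, time)."""

    replica_id: str
    bmus: np.ndarray  # (n_frames,) neuron ids
    distances: np.ndarray  # (n_frames,) frame->BMU Euclidean distance
    times_ps: np.ndarray | None = None
    force: np.ndarray | None = None  # kJ mol^-1 nm^-1
    extension: np.ndarray | None = None  # nm

    def __post_init__(self) -> None:
        self.bmus = np.asarray(self.bmus, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        n = len(self.bmus)
        if n < 2:
            raise ValueError("a path trace needs more than one frame")
        if len(self.distances) != n:
            raise ValueError("distances must match frame count")
        for name in ("times_ps", "force", "extension"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise ValueError(f"{name} length {len(v)} != {n} frames")
                setattr(self, name, v)

    @property
    def n_frames(self) -> int:
        return len(self.bmus)

    def to_csv(self, path: str | Path) -> None:
        cols = {
            "frame": np.arange(self.n_frames),
            "time_ps": self.times_ps if self.times_ps is not None else np.arange(self.n_frames, dtype=float),
            "bmu": self.bmus,
            "dist": self.distances,
        }
        if self.force is not None:
            cols["force"] = self.force
        if self.extension is not None:
            cols["extension"] = self.extension
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, replica_id: str | None = None) -> "PathTrace":
        df = pd.read_csv(path)
        return cls(
            replica_id=replica_id or Path(path).stem,
            bmus=df["bmu"].to_numpy(),
            distances=df["dist"].to_numpy(),
            times_ps=df["time_ps"].to_numpy() if "time_ps" in df else None,
            force=df["force"].to_numpy() if "force" in df else None,
            extension=df["extension"].to_numpy() if "extension" in df else None,
        )


def trace_path(
    model: SOMModel,
    features: FeatureMatrix,
    force: np.ndarray | None = None,
    extension: np.ndarray | None = None,
) -> PathTrace:
    """Map one replica onto the SOM: BMU of every frame, in frame order."""
    bmus, dists = assign_bmus(model, features.values)
    return PathTrace(
        replica_id=features.replica_id,
        bmus=bmus,
        distances=dists,
        times_ps=features.times_ps,
        force=force,
        extension=extension,
    )


def bmu_pair_distance(model: SOMModel, a: int, b: int) -> float:
    """Mean square deviation between the codebook vectors of neurons a and
    b: (1/P) Σ_k (w_a,k − w_b,k)².  Squared feature units (nm²)."""
    n = model.n_neurons
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"neuron ids must be in 0..{n - 1}")
    diff = model.codebook[a] - model.codebook[b]
    return float(np.mean(diff**2))


def _codebook_msd_matrix(model: SOMModel) -> np.ndarray:
    cb = model.codebook
    sq = ((cb[:, None, :] - cb[None, :, :]) ** 2).mean(-1)
    return sq


def path_distance(
    a: PathTrace,
    b: PathTrace,
    model: SOMModel,
    resample: bool = False,
) -> float:
    """Pathway distance: frame-wise mean of the codebook mean-square
    deviations between the two routes' BMUs.

    Traces of unequal length raise unless ``resample=True``, in which case
    the shorter trace is resampled by nearest-time index onto the longer
    one's frame grid before applying the formula.
    """
    sa, sb = a.bmus, b.bmus
    if len(sa) != len(sb):
        if not resample:
            raise ValueError(
                f"trace lengths differ ({len(sa)} vs {len(sb)}); enable resample"
            )
        if len(sa) < len(sb):
            sa = _resample_bmus(a, b)
        else:
            sb = _resample_bmus(b, a)
    msd = _codebook_msd_matrix(model)
    return float(msd[sa, sb].mean())


def _resample_bmus(short: PathTrace, long: PathTrace) -> np.ndarray:
    """Nearest-time resampling of the shorter trace onto the longer grid;
    falls back to fractional frame index when times are absent."""
    if short.times_ps is not None and long.times_ps is not None:
        t_short, t_long = short.times_ps, long.times_ps
    else:
        t_short = np.linspace(0.0, 1.0, short.n_frames)
        t_long = np.linspace(0.0, 1.0, long.n_frames)
    idx = np.abs(t_short[None, :] - t_long[:, None]).argmin(axis=1)
    return short.bmus[idx]


@dataclass
class PathwayClustering:
    replica_ids: list[str]
    distance_matrix: np.ndarray
    linkage_matrix: np.ndarray
    labels: np.ndarray  # cut labels, 1..n
    n_clusters: int
    method: str = "average"


def cluster_paths(
    traces: list[PathTrace],
    model: SOMModel,
    n: int = 2,
    resample: bool = False,
) -> PathwayClustering:
    """Average-linkage hierarchical clustering of replicas by pathway
    distance; the full tree is retained so the dendrogram can be inspected
    before settling on a cut."""
    if len(traces) < 2:
        raise ValueError("need at least 2 traces to cluster")
    m = len(traces)
    msd = _codebook_msd_matrix(model)  # shared across all pairs
    equal_len = len({t.n_frames for t in traces}) == 1
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if equal_len:
                D[i, j] = D[j, i] = float(msd[traces[i].bmus, traces[j].bmus].mean())
            else:
                D[i, j] = D[j, i] = path_distance(traces[i], traces[j], model, resample=resample)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=n, criterion="maxclust")
    return PathwayClustering(
        replica_ids=[t.replica_id for t in traces],
        distance_matrix=D,
        linkage_matrix=Z,
        labels=labels,
        n_clusters=int(len(np.unique(labels))),
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage tree as a Newick string (branch lengths from
    merge heights)."""
    tree = to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def retrace(
    model: SOMModel,
    features: FeatureMatrix,
    training_distances: np.ndarray | None = None,
    force: np.ndarray | None = None,
    extension: np.ndarray | None = None,
) -> tuple[PathTrace, dict]:
    """Assign held-out frames (e.g. a lower pulling speed run) to the
    neurons of an already-trained map.

    Mechanically identical to :func:`trace_path`; additionally summarizes
    the frame→BMU distance sample and, when the training run's distances
    are supplied, compares the two distributions (medians plus a
    two-sample Kolmogorov–Smirnov statistic).  Comparable distributions
    indicate the held-out frames are well represented by the map even
    though they were not used for training.
    """
    trace = trace_path(model, features, force=force, extension=extension)
    stats: dict = {
        "median_distance": float(np.median(trace.distances)),
        "mean_distance": float(np.mean(trace.distances)),
    }
    if training_distances is not None:
        training_distances = np.asarray(training_distances, float)
        ks = ks_2samp(trace.distances, training_distances)
        stats.update(
            {
                "training_median_distance": float(np.median(training_distances)),
                "ks_statistic": float(ks.statistic),
                "ks_pvalue": float(ks.pvalue),
            }
        )
    return trace, stats
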