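"""Self-organizing map on a non-periodic hexagonal lattice.

A SOM is a grid of neurons, each holding a codebook vector in the input
feature space.  Training presents the data repeatedly; each presentation
finds the best matching unit (BMU, the neuron with the closest codebook
vector) and pulls the BMU and its lattice neighbours toward the sample,
with both the learning rate and the neighbourhood radius decaying over the
run.  On a sheet-shaped (non-periodic) map the end states of a monotonic
process segregate naturally into opposite corners, which is what makes the
map a readable chart of an unfolding reaction.

Training is the online Kohonen rule implemented here directly (the inner
loop is numba-compiled); hierarchical clustering of the trained neurons and
silhouette scoring go through scipy/scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

from .features import FeatureMatrix, drmsd

__all__ = [
    "SOMModel",
    "NeuronClustering",
    "hex_positions",
    "train_som",
    "assign_bmu",
    "assign_bmus",
    "centrotypes",
    "neuron_quality",
    "cluster_neurons",
]

#: Lattice distance below which two neurons count as neighbours.  Unit hex
#: spacing puts the six nearest neighbours at distance 1.0 exactly.
ADJACENCY_THRESHOLD = 1.01


def hex_positions(rows: int, cols: int) -> np.ndarray:
    """2-D neuron positions for a hexagonal sheet: odd rows shifted by
    +0.5 in x, rows spaced sqrt(3)/2 apart.  Neuron id = row*cols + col."""
    pos = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c, 0] = c + 0.5 * (r % 2)
            pos[r * cols + c, 1] = r * np.sqrt(3.0) / 2.0
    return pos


@dataclass
class SOMModel:
    rows: int
    cols: int
    codebook: np.ndarray  # (n_neurons, P), feature units (nm)
    seed: int
    n_epochs: int = 500
    lr_start: float = 0.05
    lr_end: float = 0.01
    radius_start: float | None = None
    radius_end: float = 1.0
    quantization_error: float = float("nan")

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.rows * self.cols:
            raise ValueError("codebook must have rows*cols neurons")
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("codebook must be finite")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def n_features(self) -> int:
        return self.codebook.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return hex_positions(self.rows, self.cols)

    def neighbors(self, neuron: int) -> np.ndarray:
        """Lattice-adjacent neuron ids (hex distance ≤ 1)."""
        pos = self.positions
        d = np.sqrt(((pos - pos[neuron]) ** 2).sum(1))
        out = np.where((d > 0) & (d < ADJACENCY_THRESHOLD))[0]
        return out

    # -- persistence: JSON header + CSV codebook, lossless round trip ------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "rows": self.rows,
            "cols": self.cols,
            "seed": self.seed,
            "n_epochs": self.n_epochs,
            "lr_start": self.lr_start,
            "lr_end": self.lr_end,
            "radius_start": self.radius_start,
            "radius_end": self.radius_end,
            "quantization_error": self.quantization_error,
            "n_features": self.n_features,
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for row in self.codebook:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        with open(path) as fh:
            header = json.loads(fh.readline())
            codebook = np.array(
                [[float(v) for v in line.split(",")] for line in fh if line.strip()]
            )
        qe = header.pop("quantization_error")
        header.pop("n_features")
        model = cls(codebook=codebook, **header)
        model.quantization_error = qe
        return model


@njit(cache=False)
def _train_kernel(data, codebook, grid_sq_dist, n_epochs, lr_start, lr_end, r_start, r_end):
    """Online Kohonen updates: samples in order, one pass per epoch,
    learning rate and Gaussian neighbourhood radius decaying linearly over
    total presentations."""
    n_samples, n_feat = data.shape
    n_neurons = codebook.shape[0]
    total = n_epochs * n_samples
    t = 0
    for _epoch in range(n_epochs):
        for s in range(n_samples):
            frac = t / max(total - 1, 1)
            lr = lr_start + (lr_end - lr_start) * frac
            radius = r_start + (r_end - r_start) * frac
            # BMU: argmin squared distance, ties to lowest id
            best = 0
            best_d = 1e300
            for n in range(n_neurons):
                d = 0.0
                for k in range(n_feat):
                    diff = codebook[n, k] - data[s, k]
                    d += diff * diff
                if d < best_d:
                    best_d = d
                    best = n
            denom = 2.0 * radius * radius
            for n in range(n_neurons):
                h = lr * np.exp(-grid_sq_dist[best, n] / denom)
                if h > 1e-6:
                    for k in range(n_feat):
                        codebook[n, k] += h * (data[s, k] - codebook[n, k])
            t += 1
    return codebook


def train_som(
    features: FeatureMatrix | np.ndarray,
    rows: int = 8,
    cols: int = 8,
    seed: int = 0,
    n_epochs: int = 500,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
    radius_start: float | None = None,
    radius_end: float = 1.0,
) -> SOMModel:
    """Train a sheet-shaped hexagonal SOM.

    The codebook is initialized uniformly at random within each feature's
    data range (seeded); the neighbourhood radius defaults to 2/3 of the
    lattice diagonal and decays linearly to ``radius_end``.  Deterministic
    given identical data, grid, hyperparameters, and seed.
    """
    data = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("features must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite feature values")
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must both be >= 2")
    n_neurons = rows * cols
    if data.shape[0] < n_neurons:
        import warnings

        warnings.warn(
            f"{data.shape[0]} frames for {n_neurons} neurons: map may be underpopulated"
        )
    pos = hex_positions(rows, cols)
    if radius_start is None:
        diag = float(np.sqrt(((pos[0] - pos[-1]) ** 2).sum()))
        radius_start = 2.0 / 3.0 * diag
    rng = np.random.default_rng(seed)
    lo, hi = data.min(axis=0), data.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(n_neurons, data.shape[1]))
    grid_sq = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    codebook = _train_kernel(
        np.ascontiguousarray(data),
        np.ascontiguousarray(codebook),
        grid_sq,
        n_epochs,
        lr_start,
        lr_end,
        radius_start,
        radius_end,
    )
    model = SOMModel(
        rows=rows,
        cols=cols,
        codebook=codebook,
        seed=seed,
        n_epochs=n_epochs,
        lr_start=lr_start,
        lr_end=lr_end,
        radius_start=radius_start,
        radius_end=radius_end,
    )
    _, dists = assign_bmus(model, data)
    model.quantization_error = float(dists.mean())
    return model


def assign_bmu(model: SOMModel, x: np.ndarray) -> tuple[int, float]:
    """Best matching unit for one feature vector: the neuron with minimal
    Euclidean codebook distance, ties broken by lowest neuron id."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_features:
        raise ValueError(f"dimension mismatch: {x.shape[0]} vs {model.n_features}")
    d = np.sqrt(((model.codebook - x) ** 2).sum(1))
    bmu = int(np.argmin(d))  # np.argmin returns the first minimum
    return bmu, float(d[bmu])


def assign_bmus(model: SOMModel, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized BMU assignment for a (n, P) matrix; same tie rule."""
    data = data.values if isinstance(data, FeatureMatrix) else np.asarray(data, float)
    if data.shape[1] != model.n_features:
        raise ValueError("dimension mismatch")
    sq = ((data[:, None, :] - model.codebook[None, :, :]) ** 2).sum(-1)
    bmus = np.argmin(sq, axis=1)
    return bmus, np.sqrt(sq[np.arange(len(bmus)), bmus])


def centrotypes(model: SOMModel, features: FeatureMatrix | np.ndarray) -> dict[int, int]:
    """For each non-empty neuron, the index of the assigned frame closest
    to the codebook vector (the neuron's representative conformation).
    Neurons with no assigned frame are absent from the result."""
    data = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    bmus, dists = assign_bmus(model, data)
    out: dict[int, int] = {}
    for neuron in np.unique(bmus):
        idx = np.where(bmus == neuron)[0]
        out[int(neuron)] = int(idx[np.argmin(dists[idx])])
    return out


def neuron_quality(
    model: SOMModel,
    features: FeatureMatrix | np.ndarray,
    max_pairs_per_neuron: int = 200,
    seed: int = 0,
) -> dict:
    """Within-neuron vs neighbour-neuron dRMSD distributions.

    Samples pairwise dRMSD between frames sharing a neuron ("intra") and
    between frames in lattice-adjacent neurons ("inter"); caps the number
    of sampled pairs per neuron (seeded) so large neurons stay tractable.
    A well-trained map shows intra well below inter: similar conformations
    segregate into single neurons.
    """
    data = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    bmus, _ = assign_bmus(model, data)
    rng = np.random.default_rng(seed)
    members = {int(n): np.where(bmus == n)[0] for n in np.unique(bmus)}
    intra, inter = [], []
    for neuron, idx in members.items():
        if len(idx) >= 2:
            all_pairs = [(a, b) for ii, a in enumerate(idx) for b in idx[ii + 1 :]]
            if len(all_pairs) > max_pairs_per_neuron:
                sel = rng.choice(len(all_pairs), max_pairs_per_neuron, replace=False)
                all_pairs = [all_pairs[s] for s in sel]
            intra.extend(drmsd(data[a], data[b]) for a, b in all_pairs)
        for nb in model.neighbors(neuron):
            if nb <= neuron or int(nb) not in members:
                continue
            jdx = members[int(nb)]
            cross = [(a, b) for a in idx for b in jdx]
            if len(cross) > max_pairs_per_neuron:
                sel = rng.choice(len(cross), max_pairs_per_neuron, replace=False)
                cross = [cross[s] for s in sel]
            inter.extend(drmsd(data[a], data[b]) for a, b in cross)
    intra_arr, inter_arr = np.asarray(intra), np.asarray(inter)
    return {
        "intra": intra_arr,
        "inter": inter_arr,
        "median_intra": float(np.median(intra_arr)) if len(intra_arr) else float("nan"),
        "median_inter": float(np.median(inter_arr)) if len(inter_arr) else float("nan"),
    }


@dataclass
class NeuronClustering:
    """Complete-linkage grouping of neurons into macrostate clusters."""

    labels: np.ndarray  # (n_neurons,) values in 1..n_clusters
    n_clusters: int
    silhouette: np.ndarray  # per-neuron silhouette in codebook space
    average_silhouette: float
    linkage_matrix: np.ndarray
    method: str = "complete"
    metric: str = "euclidean"


def cluster_neurons(model: SOMModel, n: int | str = "auto") -> NeuronClustering:
    """Group neurons into a small number of clusters by agglomerative
    hierarchical clustering of the codebook vectors (Euclidean distance,
    complete linkage).

    With ``n="auto"`` the cut is chosen by silhouette profile: maximize the
    average silhouette width over 2..n_neurons−1, breaking near-ties
    (within 0.01) in favour of the cut with the fewest neurons scoring a
    negative silhouette.
    """
    Z = linkage(model.codebook, method="complete", metric="euclidean")

    def cut(k: int) -> tuple[np.ndarray, np.ndarray, float]:
        labels = fcluster(Z, t=k, criterion="maxclust")
        sil = silhouette_samples(model.codebook, labels, metric="euclidean")
        return labels, sil, float(sil.mean())

    if n == "auto":
        best = None
        for k in range(2, model.n_neurons):
            labels, sil, avg = cut(k)
            n_neg = int((sil < 0).sum())
            if best is None:
                best = (k, labels, sil, avg, n_neg)
                continue
            _, _, _, best_avg, best_neg = best
            if avg > best_avg + 0.01:
                best = (k, labels, sil, avg, n_neg)
            elif abs(avg - best_avg) <= 0.01 and n_neg < best_neg:
                best = (k, labels, sil, avg, n_neg)
        k, labels, sil, avg, _ = best
    else:
        k = int(n)
        if not (2 <= k <= model.n_neurons - 1):
            raise ValueError(f"n must be in 2..{model.n_neurons - 1}")
        labels, sil, avg = cut(k)
    return NeuronClustering(
        labels=labels,
        n_clusters=int(len(np.unique(labels))),
        silhouette=sil,
        average_silhouette=avg,
        linkage_matrix=Z,
    )
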