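"""Native-contact distance featurization of protein conformations.

Conformations are described by the set of pairwise distances between
per-residue reference atoms (Cβ, falling back to Cα for glycine) that lie
below a cutoff in the native folded structure.  Using internal distances
instead of Cartesian coordinates makes every downstream comparison
superposition-free, which matters for unfolding trajectories where global
alignment is ill-defined.  The default cutoff of 1.0 nm is in the range
where a Cβ contact matrix suffices to reconstruct a protein conformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "ContactPairSet",
    "FeatureMatrix",
    "load_structure",
    "select_native_pairs",
    "extract_features",
    "drmsd",
]

#: PDB coordinates are in Å; everything in this package is in nm.
ANGSTROM_TO_NM = 0.1


@dataclass(frozen=True)
class Structure:
    """One reference coordinate per residue, in nm.

    Parameters
    ----------
    residue_ids : residue identifiers (resid) in chain order.
    residue_names : three-letter residue names, same order.
    coordinates : (n_residues, 3) array in nm.
    model_index : which model of a multi-model file the coordinates came
        from (1-based, as in the PDB format); 0 for single-model sources.
    """

    residue_ids: tuple[int, ...]
    residue_names: tuple[str, ...]
    coordinates: np.ndarray
    model_index: int = 1
    gly_to_ca: bool = True

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n_residues, 3) array")
        if coords.shape[0] != len(self.residue_ids):
            raise ValueError("one coordinate per residue required")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass(frozen=True)
class ContactPairSet:
    """Residue-index pairs in native contact, with their native distances.

    Pairs are 0-based indices into the structure's residue list, stored
    with i < j in (i, j)-lexicographic order; ``native_distances`` are in
    nm and all strictly below ``cutoff``.
    """

    cutoff: float
    pairs: np.ndarray  # (n_pairs, 2) int
    native_distances: np.ndarray  # (n_pairs,) nm

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        dists = np.asarray(self.native_distances, dtype=float).ravel()
        if pairs.shape[0] != dists.shape[0]:
            raise ValueError("pairs and native_distances length mismatch")
        if pairs.size and not np.all(pairs[:, 0] < pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        if np.any(dists >= self.cutoff):
            raise ValueError("native distances must be strictly below cutoff")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "native_distances", dists)

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "i": self.pairs[:, 0],
                "j": self.pairs[:, 1],
                "native_distance_nm": self.native_distances,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cutoff: float | None = None) -> "ContactPairSet":
        df = pd.read_csv(path)
        d = df["native_distance_nm"].to_numpy()
        if cutoff is None:
            # smallest round cutoff consistent with the stored distances
            cutoff = float(np.ceil(d.max() * 10) / 10) if len(d) else 1.0
        return cls(cutoff=cutoff, pairs=df[["i", "j"]].to_numpy(), native_distances=d)


@dataclass
class FeatureMatrix:
    """Frames × native-pair distances (nm) plus frame metadata."""

    values: np.ndarray  # (n_frames, n_pairs)
    replica_id: str = "replica"
    times_ps: np.ndarray | None = None
    stride: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x pairs)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")
        if self.times_ps is not None:
            self.times_ps = np.asarray(self.times_ps, dtype=float)
            if self.times_ps.shape[0] != self.values.shape[0]:
                raise ValueError("times_ps length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values)
        df.insert(0, "time_ps", self.times_ps if self.times_ps is not None else np.arange(self.n_frames))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, replica_id: str | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        times = df.pop("time_ps").to_numpy() if "time_ps" in df else None
        return cls(
            values=df.to_numpy(dtype=float),
            replica_id=replica_id or Path(path).stem,
            times_ps=times,
            source=str(path),
        )


def _reference_atom_coordinates(atomgroup, gly_to_ca: bool):
    """Pick one Cβ (Cα for Gly when allowed) per residue from an MDAnalysis
    AtomGroup; returns (ids, names, selected AtomGroup)."""
    import MDAnalysis as mda  # noqa: F401  (runtime dependency)

    sel_atoms = []
    ids, names = [], []
    for res in atomgroup.residues:
        cb = res.atoms.select_atoms("name CB")
        if len(cb) == 0 and (gly_to_ca or res.resname.strip() == "GLY"):
            if not gly_to_ca:
                raise ValueError(
                    f"residue {res.resname}{res.resid} has no CB atom and "
                    "gly_to_ca fallback is disabled"
                )
            cb = res.atoms.select_atoms("name CA")
        if len(cb) == 0:
            raise ValueError(
                f"residue {res.resname}{res.resid} has no usable reference atom (CB/CA)"
            )
        sel_atoms.append(cb[0])
        ids.append(int(res.resid))
        names.append(str(res.resname))
    import MDAnalysis

    group = MDAnalysis.AtomGroup(sel_atoms)
    return ids, names, group


def load_structure(path: str | Path, model_index: int = 1, gly_to_ca: bool = True) -> Structure:
    """Load a (possibly multi-model) PDB and return per-residue reference
    coordinates in nm.

    Parameters
    ----------
    path : PDB file.
    model_index : 1-based model number for NMR-style multi-model files.
    gly_to_ca : use Cα as the reference atom for residues lacking Cβ
        (glycine).  With ``False`` such residues raise instead.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    n_models = len(u.trajectory)
    if not (1 <= model_index <= n_models):
        raise IndexError(f"model_index {model_index} out of range 1..{n_models}")
    u.trajectory[model_index - 1]
    protein = u.select_atoms("protein") or u.atoms
    ids, names, group = _reference_atom_coordinates(protein, gly_to_ca)
    coords = group.positions * ANGSTROM_TO_NM
    return Structure(
        residue_ids=tuple(ids),
        residue_names=tuple(names),
        coordinates=coords,
        model_index=model_index,
        gly_to_ca=gly_to_ca,
    )


def select_native_pairs(native: Structure, cutoff: float = 1.0) -> ContactPairSet:
    """All residue pairs i < j whose native reference-atom distance is
    strictly below ``cutoff`` (nm), in (i, j)-lexicographic order."""
    if cutoff <= 0:
        return ContactPairSet(cutoff=max(cutoff, 1e-12), pairs=np.empty((0, 2), int), native_distances=np.empty(0))
    if native.n_residues < 2:
        raise ValueError("need at least 2 residues to select pairs")
    coords = native.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(native.n_residues, k=1)
    mask = dist[iu] < cutoff
    pairs = np.column_stack([iu[0][mask], iu[1][mask]])
    return ContactPairSet(cutoff=cutoff, pairs=pairs, native_distances=dist[iu][mask])


def pair_distances(coordinates: np.ndarray, pairs: ContactPairSet) -> np.ndarray:
    """Distances (nm) for the pair set from one (n_residues, 3) coordinate set."""
    coords = np.asarray(coordinates, dtype=float)
    d = coords[pairs.pairs[:, 0]] - coords[pairs.pairs[:, 1]]
    return np.sqrt((d**2).sum(axis=1))


def extract_features(
    topology: str | Path,
    pairs: ContactPairSet,
    trajectory: str | Path | Sequence[str | Path] | None = None,
    stride: int = 1,
    replica_id: str | None = None,
    gly_to_ca: bool = True,
) -> FeatureMatrix:
    """Extract the native-pair distance matrix from a trajectory.

    ``topology`` is a PDB sharing the reference residue list; ``trajectory``
    may be XTC/DCD/TRR or a multi-frame PDB (``None`` reads frames from the
    topology file itself).  ``stride`` keeps frames 0, stride, 2·stride, …
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory is None:
            u = mda.Universe(str(topology))
        else:
            traj = [str(t) for t in trajectory] if isinstance(trajectory, (list, tuple)) else str(trajectory)
            u = mda.Universe(str(topology), traj)
    if len(u.trajectory) == 0:
        raise ValueError("empty trajectory")
    protein = u.select_atoms("protein") or u.atoms
    _, _, group = _reference_atom_coordinates(protein, gly_to_ca)
    n_res = len(group)
    if pairs.pairs.size and pairs.pairs.max() >= n_res:
        raise ValueError(
            f"topology has {n_res} residues but pair set indexes up to {pairs.pairs.max()}"
        )
    rows, times = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # readers without dt metadata warn per frame
        for ts in u.trajectory[::stride]:
            coords = group.positions * ANGSTROM_TO_NM
            rows.append(pair_distances(coords, pairs))
            times.append(float(ts.time))
    return FeatureMatrix(
        values=np.asarray(rows),
        replica_id=replica_id or Path(str(topology)).stem,
        times_ps=np.asarray(times),
        stride=stride,
        source=str(trajectory if trajectory is not None else topology),
    )


def drmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Distance RMSD between two feature vectors:
    sqrt((1/P) Σ_k (a_k − b_k)²).  Symmetric, non-negative,
    superposition-free."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))
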