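"""Structural-alphabet encoding of local backbone geometry.

Every overlapping 4-residue fragment of a conformation is assigned the
letter of the nearest prototype in a small alphabet of canonical fragment
geometries.  Comparing the per-position letter distribution of the
ensemble in a neuron against the folded-state distribution then gives a
per-fragment divergence profile that localizes where along the chain a
neuron's conformations have departed from the native fold.

The fragment descriptor used throughout is the vector of the three
non-adjacent reference-atom distances (d13, d14, d24) in nm, which fixes
the fragment geometry up to chirality.  Alphabets are input data (CSV of
letter + descriptor); a synthetic 25-letter alphabet spanning
helix-to-extended geometries ships as the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

__all__ = [
    "StructuralAlphabet",
    "fragment_descriptor",
    "encode_fragments",
    "letter_counts",
    "fragment_divergence",
    "make_synthetic_alphabet",
    "load_default_alphabet",
]

#: Cα–Cα virtual bond length used for ideal fragments (nm).
CA_CA_BOND = 0.38


@dataclass(frozen=True)
class StructuralAlphabet:
    letters: tuple[str, ...]
    descriptors: np.ndarray  # (n_letters, D)

    def __post_init__(self) -> None:
        desc = np.asarray(self.descriptors, dtype=float)
        if len(self.letters) < 2:
            raise ValueError("an alphabet needs at least 2 letters")
        if desc.shape[0] != len(self.letters):
            raise ValueError("one descriptor per letter required")
        if not np.all(np.isfinite(desc)):
            raise ValueError("descriptors must be finite")
        object.__setattr__(self, "descriptors", desc)

    def __len__(self) -> int:
        return len(self.letters)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StructuralAlphabet":
        df = pd.read_csv(path)
        letters = tuple(df["letter"].astype(str))
        desc = df.drop(columns=["letter"]).to_numpy(dtype=float)
        return cls(letters=letters, descriptors=desc)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.descriptors, columns=[f"d{k}" for k in range(self.descriptors.shape[1])])
        df.insert(0, "letter", list(self.letters))
        df.to_csv(path, index=False)


def fragment_descriptor(coords: np.ndarray) -> np.ndarray:
    """Descriptor of one 4-residue fragment: distances (d13, d14, d24)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (4, 3):
        raise ValueError("a fragment is 4 residues x 3 coordinates")
    return np.array(
        [
            np.linalg.norm(coords[0] - coords[2]),
            np.linalg.norm(coords[0] - coords[3]),
            np.linalg.norm(coords[1] - coords[3]),
        ]
    )


def encode_fragments(coordinates: np.ndarray, alphabet: StructuralAlphabet) -> str:
    """Encode a conformation as a letter string of length n_residues − 3:
    each overlapping 4-residue fragment gets the nearest prototype letter
    (Euclidean distance in descriptor space, ties to the first letter)."""
    coords = np.asarray(coordinates, dtype=float)
    n = coords.shape[0]
    if n < 4:
        raise ValueError("need at least 4 residues to encode fragments")
    out = []
    for i in range(n - 3):
        desc = fragment_descriptor(coords[i : i + 4])
        d = ((alphabet.descriptors - desc) ** 2).sum(axis=1)
        out.append(alphabet.letters[int(np.argmin(d))])
    return "".join(out)


def letter_counts(strings: list[str], alphabet: StructuralAlphabet) -> np.ndarray:
    """(n_positions, n_letters) counts from equal-length letter strings."""
    if not strings:
        raise ValueError("no strings given")
    n_pos = len(strings[0])
    if any(len(s) != n_pos for s in strings):
        raise ValueError("letter strings must have equal length")
    index = {letter: k for k, letter in enumerate(alphabet.letters)}
    counts = np.zeros((n_pos, len(alphabet)), dtype=float)
    for s in strings:
        for p, ch in enumerate(s):
            if ch not in index:
                raise ValueError(f"letter {ch!r} not in alphabet")
            counts[p, index[ch]] += 1
    return counts


def fragment_divergence(
    neuron_counts: np.ndarray,
    reference_counts: np.ndarray,
    pseudocount: float | None = None,
) -> np.ndarray:
    """Per-fragment-position Jensen–Shannon divergence (base 2, in [0, 1])
    between a neuron's letter distribution and the folded-state reference.

    ``pseudocount`` defaults to 1/(total sample size of the smaller of the
    two ensembles); it regularizes empty letters so the divergence is zero
    iff the (smoothed) distributions coincide.
    """
    p = np.asarray(neuron_counts, dtype=float)
    q = np.asarray(reference_counts, dtype=float)
    if p.shape != q.shape:
        raise ValueError("count matrices must share shape (positions x letters)")
    if pseudocount is None:
        n_min = min(p.sum(axis=1).max(), q.sum(axis=1).max())
        pseudocount = 1.0 / max(n_min, 1.0)
    out = np.empty(p.shape[0])
    for pos in range(p.shape[0]):
        pp = p[pos] + pseudocount
        qq = q[pos] + pseudocount
        # scipy returns the JS *distance* (sqrt of the divergence); rounding
        # can push a zero divergence infinitesimally negative -> NaN
        with np.errstate(invalid="ignore"):
            dist = jensenshannon(pp, qq, base=2)
        out[pos] = dist**2 if np.isfinite(dist) else 0.0
    return np.clip(out, 0.0, 1.0)


def make_synthetic_alphabet(n_theta: int = 5, n_alpha: int = 5) -> StructuralAlphabet:
    """Synthetic fragment alphabet: ideal 4-residue backbones on a grid of
    pseudo-bond-angle θ (bend at the two inner residues) and
    pseudo-dihedral α, covering compact helical to extended geometries.

    This is a stand-in alphabet constructed from ideal geometry, not a
    literature-derived fragment library; real alphabets can be supplied as
    CSV via :meth:`StructuralAlphabet.from_csv`.
    """
    # the distance descriptor is blind to chirality, so the dihedral grid
    # stays in [0, 180] to keep all prototypes distinct
    thetas = np.linspace(np.deg2rad(85.0), np.deg2rad(155.0), n_theta)
    alphas = np.linspace(np.deg2rad(10.0), np.deg2rad(175.0), n_alpha)
    letters, descs = [], []
    abc = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    k = 0
    for theta in thetas:
        for alpha in alphas:
            coords = _ideal_fragment(theta, alpha)
            letters.append(abc[k % 26] if k < 26 else f"x{k}")
            descs.append(fragment_descriptor(coords))
            k += 1
    return StructuralAlphabet(letters=tuple(letters), descriptors=np.asarray(descs))


def _ideal_fragment(theta: float, alpha: float) -> np.ndarray:
    """4 reference-atom positions with bond length CA_CA_BOND, bond angle
    theta at residues 2 and 3, dihedral alpha about the 2–3 bond."""
    b = CA_CA_BOND
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([b, 0.0, 0.0])
    p2 = p1 + b * np.array([-np.cos(theta), np.sin(theta), 0.0])
    # place p3 at angle theta from the 2->1 direction, rotated by alpha
    # about the 1->2 axis
    e12 = (p2 - p1) / np.linalg.norm(p2 - p1)
    ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(e12, ref)
    u /= np.linalg.norm(u)
    v = np.cross(e12, u)
    d = -np.cos(theta) * e12 + np.sin(theta) * (np.cos(alpha) * u + np.sin(alpha) * v)
    p3 = p2 + b * d
    return np.vstack([p0, p1, p2, p3])


def load_default_alphabet() -> StructuralAlphabet:
    """The packaged synthetic 25-letter alphabet."""
    with resources.as_file(
        resources.files("pathsom").joinpath("data/synthetic_alphabet_25.csv")
    ) as path:
        return StructuralAlphabet.from_csv(path)
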