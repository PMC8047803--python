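"""Ground-truth-labelled synthetic unfolding data.

Real steered-MD unfolding of a small domain proceeds by rupture of groups
of native contacts in a pathway-specific order.  The generator reproduces
exactly that statistical structure, directly in the feature space the
method consumes: native contacts are partitioned into named blocks of
consecutive residues, each pathway label scripts a rupture order over the
blocks, and each block's distances interpolate from native to a broken
multiple of native over that block's window of the run, under i.i.d.
Gaussian noise.  Pulling force is a noisy baseline with an optional
scripted peak (the signature of a mechanical intermediate) on one pathway;
extension grows linearly.  Because rupture order, noise, and the force
peak are scripted, every downstream stage can be scored against known
ground truth.

No force field and no thermodynamics: the generator targets the
statistical structure of the data, not its physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import ContactPairSet, FeatureMatrix, Structure, select_native_pairs

__all__ = [
    "ToyUnfoldingSpec",
    "ToyReplica",
    "ToyDataset",
    "generate_toy_native",
    "generate_replica",
    "generate_dataset",
]

#: Distances never drop below this (nm): keeps noisy features physical.
MIN_DISTANCE = 0.05

#: Sampling interval emulated by the generator (one frame per 100 ps).
FRAME_INTERVAL_PS = 100.0


@dataclass(frozen=True)
class ToyUnfoldingSpec:
    """Parameters of the synthetic two-pathway unfolding experiment.

    Defaults describe the study conditions used throughout the test suite:
    a 24-residue compact bead chain whose native contacts split into three
    blocks (N-lobe, core, C-hairpin), two pathway scripts that differ in
    whether the C-terminal hairpin or the N-terminal lobe ruptures first,
    50 frames per replica (one per 100 ps), contacts breaking to 3× their
    native distance, Gaussian feature noise of 5% of the mean native
    distance, and a force peak of 200 on top of a baseline of 300
    kJ mol⁻¹ nm⁻¹ inside the 30–50% window of the run, carried only by
    pathway-1 replicas (the intermediate-bearing route).
    """

    n_residues: int = 24
    blocks: tuple[tuple[str, tuple[int, int]], ...] = (
        ("N-lobe", (0, 7)),
        ("core", (8, 15)),
        ("C-hairpin", (16, 23)),
    )
    pathway_orders: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("pathway1", ("C-hairpin", "N-lobe", "core")),
        ("pathway2", ("N-lobe", "C-hairpin", "core")),
    )
    n_frames: int = 50
    broken_multiplier: float = 3.0
    noise_frac: float = 0.05  # sigma as a fraction of the mean native distance
    cutoff: float = 1.0
    bead_spacing: float = 0.4  # nm, native lattice spacing
    force_baseline: float = 300.0  # kJ mol^-1 nm^-1
    force_peak_amplitude: float = 200.0
    force_noise_sd: float = 20.0
    peak_window: tuple[float, float] = (0.3, 0.5)  # fraction of the run
    intermediate_pathway: str = "pathway1"
    max_extension: float = 24.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("need at least 8 residues")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        covered = sorted(r for _, (lo, hi) in self.blocks for r in range(lo, hi + 1))
        if covered != list(range(self.n_residues)):
            raise ValueError("blocks must partition the residue range")
        names = [name for name, _ in self.blocks]
        for label, order in self.pathway_orders:
            if sorted(order) != sorted(names):
                raise ValueError(f"rupture order for {label!r} is not a permutation of blocks")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.pathway_orders)

    def order_for(self, label: str) -> tuple[str, ...]:
        for lab, order in self.pathway_orders:
            if lab == label:
                return order
        raise KeyError(f"unknown pathway label {label!r}")

    def block_of_residue(self, residue: int) -> str:
        for name, (lo, hi) in self.blocks:
            if lo <= residue <= hi:
                return name
        raise IndexError(residue)


def generate_toy_native(spec: ToyUnfoldingSpec) -> tuple[Structure, ContactPairSet]:
    """Deterministic compact native conformation: beads on a serpentine
    walk through a cubic lattice (spacing ``bead_spacing``), which packs
    the chain so the native contact set is rich and block-structured."""
    side = int(np.ceil(spec.n_residues ** (1.0 / 3.0)))
    coords = np.zeros((spec.n_residues, 3))
    k = 0
    for z in range(side):
        for y in range(side):
            ys = y if z % 2 == 0 else side - 1 - y
            xs = range(side) if ys % 2 == (0 if z % 2 == 0 else 1) else range(side - 1, -1, -1)
            for x in xs:
                if k >= spec.n_residues:
                    break
                coords[k] = (x * spec.bead_spacing, ys * spec.bead_spacing, z * spec.bead_spacing)
                k += 1
    native = Structure(
        residue_ids=tuple(range(1, spec.n_residues + 1)),
        residue_names=("ALA",) * spec.n_residues,
        coordinates=coords,
        model_index=0,
    )
    pairs = select_native_pairs(native, cutoff=spec.cutoff)
    n_blocks_hit = len({spec.block_of_residue(int(i)) for i in pairs.pairs[:, 0]})
    if n_blocks_hit < 3:
        raise ValueError("degenerate spec: fewer than 3 blocks carry native contacts")
    return native, pairs


def _pair_blocks(spec: ToyUnfoldingSpec, pairs: ContactPairSet) -> list[str]:
    """Block membership of each pair (block of its lower residue index);
    this rule partitions the pair set."""
    return [spec.block_of_residue(int(i)) for i in pairs.pairs[:, 0]]


@dataclass
class ToyReplica:
    features: FeatureMatrix
    force: np.ndarray
    extension: np.ndarray
    label: str


@dataclass
class ToyDataset:
    spec: ToyUnfoldingSpec
    native: Structure
    pairs: ContactPairSet
    replicas: list[ToyReplica]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.replicas]


def generate_replica(
    spec: ToyUnfoldingSpec,
    label: str,
    seed: int,
    pairs: ContactPairSet | None = None,
    frames_multiplier: int = 1,
) -> ToyReplica:
    """One synthetic pulling replica following a scripted pathway.

    Each block's pair distances interpolate linearly from native to
    ``broken_multiplier`` × native over that block's window of the run
    (windows are the equal thirds of the run in the pathway's rupture
    order, expressed as run fractions so a ``frames_multiplier`` of 10
    emulates a 10×-longer low-pulling-speed run of the same script).
    Gaussian noise of σ = ``noise_frac`` × mean native distance is added
    and distances clipped at a small physical floor.  Force is baseline +
    noise, plus the peak amplitude inside ``peak_window`` when the label
    is the intermediate-bearing pathway; extension grows linearly to
    ``max_extension``.
    """
    if pairs is None:
        _, pairs = generate_toy_native(spec)
    order = spec.order_for(label)
    blocks = _pair_blocks(spec, pairs)
    rank = {name: pos for pos, name in enumerate(order)}
    n_blocks = len(order)
    n_frames = spec.n_frames * frames_multiplier
    u = np.linspace(0.0, 1.0, n_frames)  # run fraction per frame
    native = pairs.native_distances
    rng = np.random.default_rng(seed)

    values = np.empty((n_frames, len(pairs)))
    for k in range(len(pairs)):
        b = rank[blocks[k]]
        progress = np.clip(u * n_blocks - b, 0.0, 1.0)
        values[:, k] = native[k] * (1.0 + (spec.broken_multiplier - 1.0) * progress)
    sigma = spec.noise_frac * float(native.mean())
    if sigma > 0:
        values = values + rng.normal(0.0, sigma, size=values.shape)
        values = np.clip(values, MIN_DISTANCE, None)

    force = spec.force_baseline + (
        rng.normal(0.0, spec.force_noise_sd, size=n_frames) if spec.force_noise_sd > 0 else 0.0
    )
    if label == spec.intermediate_pathway:
        lo, hi = spec.peak_window
        force = force + np.where((u >= lo) & (u <= hi), spec.force_peak_amplitude, 0.0)
    extension = u * spec.max_extension
    times = np.arange(n_frames) * FRAME_INTERVAL_PS
    feats = FeatureMatrix(
        values=values,
        replica_id=f"{label}_s{seed}",
        times_ps=times,
        source="synthetic",
    )
    return ToyReplica(features=feats, force=force, extension=extension, label=label)


def generate_dataset(
    spec: ToyUnfoldingSpec,
    n_per_pathway: Sequence[int] | dict[str, int],
    seed: int | None = None,
    frames_multiplier: int = 1,
) -> ToyDataset:
    """A full labelled dataset with per-replica seeds derived
    deterministically from the master seed; same seed → identical data."""
    if seed is None:
        seed = spec.seed
    native, pairs = generate_toy_native(spec)
    if isinstance(n_per_pathway, dict):
        counts = [n_per_pathway[label] for label in spec.labels]
    else:
        counts = list(n_per_pathway)
    if len(counts) != len(spec.labels):
        raise ValueError("one replica count per pathway label required")
    if any(c < 1 for c in counts):
        raise ValueError("n_per_pathway entries must be >= 1")
    replicas = []
    idx = 0
    for label, count in zip(spec.labels, counts):
        for _ in range(count):
            child = int((seed * 100003 + idx * 7919 + 1) % (2**31 - 1))
            rep = generate_replica(spec, label, child, pairs=pairs, frames_multiplier=frames_multiplier)
            rep.features.replica_id = f"rep{idx:03d}_{label}"
            replicas.append(rep)
            idx += 1
    return ToyDataset(spec=spec, native=native, pairs=pairs, replicas=replicas)
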