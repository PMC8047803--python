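# Methods

## Model and assumptions

`pathsom` treats a set of pulling trajectories as samples of a continuous
unfolding process and asks two questions: which conformational states are
visited, and in what order. The state description is the vector of native
contact distances — every residue pair whose reference atoms (Cβ; Cα for
glycine) are strictly closer than a cutoff (default 1.0 nm) in the folded
structure. This representation assumes that loss of native contacts is the
informative signal of unfolding: non-native contacts formed transiently
along the way are invisible to it, by design. Distances are in nm
throughout; PDB Å inputs are converted on load. Feature scaling is off by
default since all features share units.

The SOM is a sheet-shaped (non-periodic) hexagonal lattice, default 8 × 8.
Non-periodicity matters: a monotone process with two end states pushes
those end states into opposite corners, making the map readable as a chart
of the reaction. Because consecutive trajectory frames are similar, a
replica traces a mostly contiguous route of best-matching units (BMUs) on
the trained map; pathway classification is clustering of those routes.

## Training procedure and defaults

The online Kohonen rule is used (no batch variant): codebook vectors are
initialized uniformly at random within each feature's data range (seeded),
then for every presented frame the BMU and its neighbours move toward the
frame by `lr · exp(−g²/2σ²)`, with g the lattice distance to the BMU.
Frames are presented in data order, one pass per epoch. Defaults, all
exposed and recorded in the model metadata:

| parameter | default | notes |
|---|---|---|
| epochs | 500 | full passes over the pooled frames |
| learning rate | 0.05 → 0.01 | linear decay over total presentations |
| neighbourhood σ | 2/3 lattice diagonal → 1.0 | linear decay, Gaussian kernel |
| init | uniform in per-feature range | seeded |
| tie-breaks | lowest neuron id | everywhere (BMU, letters, clusters) |

Neighbourhood updates below 10⁻⁶·lr are skipped; the inner loop is
numba-compiled and bitwise deterministic for a given seed, data, and grid.
With a Gaussian kernel the final σ = 1 keeps adjacent neurons weakly
coupled, which preserves map smoothness on realistic grids; on toy maps
(2 × 2) it prevents full convergence, so convergence-limit tests shrink
the final radius explicitly.

Lattice convention: odd rows offset +0.5 in x, rows √3/2 apart, unit
spacing; "neighbouring neurons" means lattice distance < 1.01 (the six
surrounding hexagons).

## Pathway distance and clustering

Neurons are grouped into macrostates by complete-linkage agglomerative
clustering of codebook vectors (Euclidean). For an automatic cut the
average silhouette width is maximized over all candidate cuts, with
near-ties (within 0.01) resolved toward the cut with fewest
negative-silhouette neurons.

Two replica routes of equal length are compared with

    D(A, B) = (1/n) Σᵢ d(Aᵢ, Bᵢ),   d(a, b) = (1/P) Σₖ (w_a,k − w_b,k)²

— the frame-wise mean of *squared* codebook deviations, kept in squared
units deliberately. Note d is a semimetric, not a metric: the strict
triangle inequality can fail for collinear codebook triples (neurons along
one grid line are nearly collinear in feature space), though the relaxed
bound D(A,B) ≤ 2·(D(A,C) + D(C,B)) always holds. At realistic trace
lengths (tens of frames) random trace triples satisfy the strict
inequality numerically. Unequal-length traces raise by default; an
explicit option resamples the shorter trace by nearest time. Pathway
families come from average-linkage clustering of the pairwise D matrix;
the full dendrogram is always emitted (Newick) because merge decisions for
minor branches are a judgement call left to the user, with the default cut
at n = 2.

## Transition graph and property maps

Transition counts pool consecutive-frame neuron pairs over all replicas,
self-transitions included (they dominate consecutive-frame data; an option
excludes them). Rows with at least one count are normalized to
probabilities; never-visited neurons keep zero rows and are flagged
isolated. Edges carry −ln p (natural log — shortest paths are base
invariant, and the base is recorded); the shortest-path distance is
asserted internally to equal both the edge-weight sum and −ln Π p within
10⁻⁹. Property maps average a per-frame scalar (typically pulling force)
over the frames in each neuron; unvisited neurons are missing (NaN), never
zero. Work profiles use the trapezoidal cumulative integral of F over
extension.

## Structural-alphabet profiles

Local backbone changes are profiled by encoding every overlapping
4-residue fragment with the nearest prototype of a structural alphabet and
comparing each neuron's per-position letter distribution to the
folded-state distribution with the Jensen–Shannon divergence (base 2,
range [0, 1], pseudocount 1/sample-size). The fragment descriptor is fixed
to the three non-adjacent reference-atom distances (d13, d14, d24), which
determines the geometry up to chirality. The packaged default
(`synthetic_alphabet_25.csv`) is a *synthetic* 25-letter alphabet built
from ideal fragments on a 5 × 5 grid of pseudo-bond-angle (85–155°) and
pseudo-dihedral (10–175°, one half-turn because the descriptor is
chirality-blind); any alphabet with the same descriptor convention can be
supplied as CSV. The module reproduces the analysis pattern, not any
specific published fragment library.

## Synthetic data: what it emulates and what it does not

The generator scripts two-pathway unfolding directly in feature space.
The native state is a deterministic serpentine bead chain on a cubic
lattice (24 residues, 0.4 nm spacing → 247 contact pairs below 1.0 nm),
partitioned into three residue blocks (N-lobe, core, C-hairpin); each
pathway label is a permutation of block rupture order; each block's
distances interpolate linearly from native to 3× native over its third of
the run, under i.i.d. Gaussian noise with σ = 5% of the mean native
distance (clipped at 0.05 nm). Force is a noisy baseline
(300 ± 20 kJ mol⁻¹ nm⁻¹) plus a 200 kJ mol⁻¹ nm⁻¹ peak inside the 30–50%
window of the run, carried only by pathway-1 replicas (the
intermediate-bearing route); extension grows linearly to 24 nm; frames are
spaced 100 ps. Defaults are fixed once as the study conditions.

What passing tests on this data demonstrate: the pipeline separates
rupture-order pathway families, localizes scripted force peaks, and is
self-consistent under retracing and resampling. What they do not
demonstrate: behaviour under non-native contact formation, force-field
physics, back-and-forth recrossing, frame-to-frame kinetic correlation of
the noise, or unequal replica lengths — real SMD data have all of these.

## Numerical choices and degenerate inputs

Strict inequality (< cutoff) for pair inclusion; boundary-equal distances
are excluded. All ties break to the lowest index. Model persistence uses a
JSON header plus full-precision decimal codebook rows (lossless round
trip). Empty feature sets, non-finite values, dimension mismatches, and
out-of-range neuron ids raise immediately with the offending quantity
named. jensenshannon's occasional NaN at numerically-zero divergence is
mapped to 0.

## Problem sizes

The test suite and the acceptance script run the study conditions at
desk scale, chosen once: five 50-replica experiments (12/38 split, 2500
frames per map) for pathway recovery; twenty independently seeded
10-replica maps for segregation and force-peak statistics; a 10×-frame
replica of the same rupture script as the low-pulling-speed analogue for
retracing checks.

## Known limitations

- The online SOM is order-sensitive; classification (not the codebook) is
  invariant to frame permutation, and this is tested, but per-neuron frame
  membership can shift between orderings.
- Small maps can topologically fold for some random initializations — a
  known SOM behaviour; on 8 × 8 maps with these data it was not observed,
  but inspecting the dRMSD quality distributions is still recommended.
- The native-contact feature space cannot distinguish conformations that
  differ only in non-native contacts.
- No dynamic-time-warping or alignment-based trace comparison; the
  frame-wise formula assumes replicas progress at comparable rates.
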