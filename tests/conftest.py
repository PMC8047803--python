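"""Shared fixtures: hand-written PDB files and session-scoped trained maps."""

from __future__ import annotations

import numpy as np
import pytest

from pathsom.som import train_som
from pathsom.synthetic import ToyUnfoldingSpec, generate_dataset

NM_TO_A = 10.0


def format_pdb_models(models, resnames=None, cb_coords=True):
    """Render multi-model PDB text from a list of (n_res, 3) coordinate
    arrays in nm.  Each residue gets an N, CA and (unless the residue is
    GLY or cb_coords is False) a CB atom; the given coordinates are the
    reference-atom positions (CB, or CA for GLY)."""
    lines = []
    n_res = len(models[0])
    resnames = resnames or ["ALA"] * n_res
    for m, coords in enumerate(models, start=1):
        if len(models) > 1:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for i, xyz in enumerate(np.asarray(coords) * NM_TO_A):
            resname = resnames[i]
            has_cb = cb_coords and resname != "GLY"
            # backbone atoms near the reference position so the residue parses
            offsets = [("N", (-0.8, 0.0, 0.0)), ("CA", (-0.4, 0.0, 0.0))]
            if has_cb:
                offsets.append(("CB", (0.0, 0.0, 0.0)))
            else:
                offsets = [("N", (-0.4, 0.0, 0.0)), ("CA", (0.0, 0.0, 0.0))]
            for name, off in offsets:
                x, y, z = xyz[0] + off[0], xyz[1] + off[1], xyz[2] + off[2]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<4s}{resname:<4s}A{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                    f"{name[0]}"
                )
                serial += 1
        lines.append("TER")
        if len(models) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_pdb(tmp_path):
    def _write(name, models, resnames=None, cb_coords=True):
        path = tmp_path / name
        path.write_text(format_pdb_models(models, resnames, cb_coords))
        return path

    return _write


@pytest.fixture(scope="session")
def toy_spec():
    return ToyUnfoldingSpec()


@pytest.fixture(scope="session")
def small_dataset(toy_spec):
    """Balanced 12-replica dataset at the default noise level."""
    return generate_dataset(toy_spec, (6, 6), seed=2)


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    data = np.vstack([r.features.values for r in small_dataset.replicas])
    return train_som(data, seed=2)


@pytest.fixture(scope="session")
def noiseless_dataset():
    spec = ToyUnfoldingSpec(noise_frac=0.0)
    return generate_dataset(spec, (6, 6), seed=3)


@pytest.fixture(scope="session")
def noiseless_model(noiseless_dataset):
    data = np.vstack([r.features.values for r in noiseless_dataset.replicas])
    return train_som(data, seed=3)
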