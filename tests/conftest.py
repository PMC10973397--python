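"""Shared fixtures.

The two trained models (single-complex overfit and the twin-site
conditioning pair) are session-scoped: they take tens of seconds each and
are reused by several tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketforge.fixtures import (
    make_conditioning_pair,
    make_overfit_complex,
)
from pocketforge.model import ModelConfig
from pocketforge.trainer import TrainConfig, fit


def rigid_transform(seed: int):
    """A random rotation + translation, as a callable on (n, 3) arrays."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q))
    shift = rng.uniform(-20, 20, 3)

    def apply(coords: np.ndarray) -> np.ndarray:
        return rot.apply(np.asarray(coords, float)) + shift

    return apply


def transform_pocket(pocket, apply):
    from pocketforge.complex_io import Atom3D, ProteinPocket

    return ProteinPocket(
        atoms=[
            Atom3D(a.element, apply(a.position[None, :])[0],
                   a.formal_charge, a.is_aromatic, a.is_in_ring)
            for a in pocket.atoms
        ],
        residue_name=list(pocket.residue_name),
        residue_number=list(pocket.residue_number),
        chain_id=list(pocket.chain_id),
        atom_name=list(pocket.atom_name),
        source_id=pocket.source_id,
    )


def transform_ligand(ligand, apply):
    from pocketforge.complex_io import Atom3D, LigandMolecule

    return LigandMolecule(
        atoms=[
            Atom3D(a.element, apply(a.position[None, :])[0],
                   a.formal_charge, a.is_aromatic, a.is_in_ring)
            for a in ligand.atoms
        ],
        bonds=list(ligand.bonds),
    )


@pytest.fixture(scope="session")
def toy_config() -> ModelConfig:
    return ModelConfig.toy(seed=0)


@pytest.fixture(scope="session")
def overfit_run(toy_config):
    """Model trained to memorize one H-bonded complex."""
    pocket, ligand, condition = make_overfit_complex(seed=7)
    result = fit(
        [(pocket, ligand, condition)],
        toy_config,
        TrainConfig(epochs=600, seed=1, learning_rate=5e-3,
                    final_learning_rate=1e-4),
    )
    return {"pocket": pocket, "ligand": ligand, "condition": condition,
            "result": result}


@pytest.fixture(scope="session")
def conditioning_run(toy_config):
    """Model trained on the twin-site pair (condition disambiguates)."""
    pair = make_conditioning_pair(seed=0)
    dataset = [(p, lig, cond) for p, lig, cond, _ in pair]
    result = fit(
        dataset,
        toy_config,
        TrainConfig(epochs=400, seed=1, learning_rate=5e-3,
                    final_learning_rate=1e-4),
    )
    return {"pair": pair, "result": result}
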