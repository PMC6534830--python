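from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from molprep.chem_model import Variant, canonical_key, mol_from_smiles
from molprep.geometry import EmbedError


class StubBackend:
    """Scriptable geometry backend: trivial embeddings, programmable energies.

    ``energy_fn`` maps a hydrogen-stripped canonical SMILES to an energy;
    molecules it does not know get ``default_energy``. Every embed call is
    logged so tests can count how many variants were actually embedded.
    """

    def __init__(self, energy_fn=None, default_energy: float = 0.0, fail_keys=()):
        self.energy_fn = energy_fn or {}
        self.default_energy = default_energy
        self.fail_keys = set(fail_keys)
        self.embed_calls: list[str] = []
        self.optimize_calls: list[str] = []

    def _key(self, mol: Chem.Mol) -> str:
        return canonical_key(Chem.RemoveHs(mol))

    def embed(self, mol: Chem.Mol, seed: int) -> Chem.Mol:
        return self.embed_multiple(mol, 1, seed)

    def embed_multiple(self, mol: Chem.Mol, n: int, seed: int) -> Chem.Mol:
        key = canonical_key(mol)
        self.embed_calls.append(key)
        if key in self.fail_keys:
            raise EmbedError(f"scripted embedding failure for {key}")
        molh = Chem.AddHs(mol)
        for c in range(n):
            conf = Chem.Conformer(molh.GetNumAtoms())
            for i in range(molh.GetNumAtoms()):
                conf.SetAtomPosition(i, (float(i), float(c), 0.0))
            molh.AddConformer(conf, assignId=True)
        return molh

    def _energy(self, mol3d: Chem.Mol) -> float:
        key = self._key(mol3d)
        if callable(self.energy_fn):
            return float(self.energy_fn(key))
        return float(self.energy_fn.get(key, self.default_energy))

    def single_point_energy(self, mol3d: Chem.Mol, conf_id: int = -1) -> float:
        return self._energy(mol3d)

    def optimize(self, mol3d: Chem.Mol, conf_id: int = -1) -> float:
        self.optimize_calls.append(self._key(mol3d))
        return self._energy(mol3d) - 1.0


@pytest.fixture
def stub_backend():
    return StubBackend()


def make_variants(smiles_list: list[str], parent_id: str = "p") -> list[Variant]:
    from molprep.chem_model import ProvenanceStep

    return [
        Variant(
            parent_id=parent_id,
            mol=mol_from_smiles(smi),
            provenance=[ProvenanceStep("ionize", f"form {i}")],
        )
        for i, smi in enumerate(smiles_list)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
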