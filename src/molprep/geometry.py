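"""Geometry backend: 3D embedding and force-field evaluation.

Two operations define the backend contract consumed by the pruning and
ring-conformer stages:

* ``embed`` / ``embed_multiple`` — distance-geometry embedding of a molecular
  graph into one or more 3D conformers (deterministic under a seed);
* ``single_point_energy`` / ``optimize`` — force-field evaluation of an
  embedded conformer, without or with geometry minimization.

The default adapter binds to RDKit: ETKDG (v2) for embedding and UFF for
energies. Tests may substitute any object with the same four methods, e.g.
a stub returning scripted energies.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem


class EmbedError(RuntimeError):
    """Raised when a molecule cannot be embedded in 3D (e.g. bridged systems)."""


class RDKitBackend:
    """ETKDG embedding + UFF energies via RDKit."""

    #: cap on UFF minimization iterations; enough for drug-like molecules
    max_iters = 500

    def embed(self, mol: Chem.Mol, seed: int) -> Chem.Mol:
        """Return a copy of ``mol`` with explicit hydrogens and one 3D conformer."""
        return self.embed_multiple(mol, 1, seed)

    def embed_multiple(self, mol: Chem.Mol, n: int, seed: int) -> Chem.Mol:
        """Return a copy of ``mol`` with explicit hydrogens and ``n`` conformers."""
        molh = Chem.AddHs(mol)
        params = AllChem.ETKDGv2()
        # seed must fit in a C int and be > 0 for reproducibility
        params.randomSeed = int(seed) % (2**31 - 1) + 1
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
        if len(conf_ids) < n:
            # retry once with random coordinates, the standard fallback
            params.useRandomCoords = True
            conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
        if len(conf_ids) == 0:
            raise EmbedError(f"embedding failed for {Chem.MolToSmiles(mol)}")
        return molh

    def single_point_energy(self, mol3d: Chem.Mol, conf_id: int = -1) -> float:
        """UFF energy of an existing conformer, no minimization."""
        ff = AllChem.UFFGetMoleculeForceField(mol3d, confId=conf_id)
        if ff is None:
            raise EmbedError("UFF parameters unavailable for molecule")
        return float(ff.CalcEnergy())

    def optimize(self, mol3d: Chem.Mol, conf_id: int = -1) -> float:
        """Minimize a conformer in place with UFF; returns the final energy."""
        ff = AllChem.UFFGetMoleculeForceField(mol3d, confId=conf_id)
        if ff is None:
            raise EmbedError("UFF parameters unavailable for molecule")
        ff.Minimize(maxIts=self.max_iters)
        return float(ff.CalcEnergy())


def conformer_coordinates(mol3d: Chem.Mol, conf_id: int = -1) -> np.ndarray:
    """(n_atoms, 3) array of a conformer's coordinates in Å."""
    return np.array(mol3d.GetConformer(conf_id).GetPositions(), dtype=float)


DEFAULT_BACKEND = RDKitBackend()
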