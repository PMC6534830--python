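"""Core chemical data types and graph-level predicates shared by all stages.

The molecular graph itself is an RDKit ``Mol``; the dataclasses here add the
bookkeeping the pipeline needs on top of it: input records, provenance of the
enumeration steps applied to a variant, and 3D conformers with energies.

A single aromaticity model (RDKit's default perception) is fixed for the
whole pipeline so that ring-count comparisons between a parent molecule and
its tautomers are made under one consistent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty about sanitization failures we handle explicitly.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: Closed set of pipeline stages a provenance step may come from.
STAGES = frozenset(
    {
        "desalt",
        "ionize",
        "tautomerize",
        "chirality",
        "cis_trans",
        "ring_conformer",
        "optimize",
    }
)


@dataclass(frozen=True)
class ProvenanceStep:
    """One step in the history of how a variant was produced."""

    stage: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {sorted(STAGES)}")

    def __str__(self) -> str:  # used verbatim in SDF Genealogy fields
        return f"{self.stage}: {self.detail}" if self.detail else self.stage


@dataclass
class MoleculeRecord:
    """One input compound: identifier plus the representation as read."""

    identifier: str
    smiles: str
    source_index: int = 0
    failed: bool = False
    failure_reason: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("identifier must be non-empty")

    def to_mol(self) -> Optional[Chem.Mol]:
        """Parse the stored SMILES; ``None`` if unparseable."""
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class Conformer3D:
    """Per-atom 3D coordinates (Å) with a force-field energy."""

    coordinates: np.ndarray
    energy: float
    optimized: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class Variant:
    """An enumerated form of a molecule with the history that produced it."""

    parent_id: str
    mol: Chem.Mol
    provenance: list[ProvenanceStep] = field(default_factory=list)
    energy: Optional[float] = None
    conformer: Optional[Conformer3D] = None
    #: hydrogen-explicit copy of ``mol`` carrying the 3D conformer, once embedded
    mol3d: Optional[Chem.Mol] = None

    def key(self) -> str:
        return canonical_key(self.mol)

    def child(self, mol: Chem.Mol, step: ProvenanceStep) -> "Variant":
        """A new variant derived from this one by one more enumeration step."""
        return Variant(
            parent_id=self.parent_id,
            mol=mol,
            provenance=[*self.provenance, step],
        )

    def copy(self) -> "Variant":
        return replace(self, provenance=list(self.provenance))


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES under the pipeline's fixed perception model.

    Raises ``ValueError`` for unparseable input instead of returning None.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def net_formal_charge(mol: Chem.Mol) -> int:
    """Sum of atomic formal charges, in units of e."""
    return sum(atom.GetFormalCharge() for atom in mol.GetAtoms())


def canonical_key(mol: Chem.Mol) -> str:
    """Canonical identity string: equal iff the molecules are the same graph.

    Invariant under atom renumbering; sensitive to connectivity, formal
    charge, hydrogen count, and stereochemical assignment.
    """
    if mol is None:
        raise ValueError("cannot compute a canonical key for a null molecule")
    return Chem.MolToSmiles(mol, isomericSmiles=True, canonical=True)


def count_aromatic_rings(mol: Chem.Mol) -> int:
    """Number of SSSR rings in which every bond is aromatic."""
    ri = mol.GetRingInfo()
    n = 0
    for ring_bonds in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring_bonds):
            n += 1
    return n


def count_chiral_centers(mol: Chem.Mol) -> int:
    """Assigned plus assignable tetrahedral stereocenters.

    Unassigned-but-assignable centers count: the tautomer filter and the
    stereo enumerator both need them.
    """
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return len(centers)


def heavy_atom_count(mol: Chem.Mol) -> int:
    return mol.GetNumHeavyAtoms()


def molecular_formula(mol: Chem.Mol) -> str:
    from rdkit.Chem import rdMolDescriptors

    return rdMolDescriptors.CalcMolFormula(mol)
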