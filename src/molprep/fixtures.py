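"""Deterministic test-fixture molecules: named exemplars and synthetic libraries.

``paper_molecules`` returns seven named compounds that between them exercise
every pipeline stage: an ionizable zwitterion precursor, a ketone with
keto/enol tautomerism, an unspecified tetrahedral center, an unspecified
double bond, a cis-disubstituted cyclohexane with competing chair/twist-boat
conformers, a featureless control, and a polyfunctional vitamin.

``synthetic_library`` constructs arbitrary-size valid SMILES libraries with
exact user-controlled fractions of salts, ionizable groups, unspecified
stereocenters, and non-aromatic rings — benchmark-style inputs with no
external downloads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_model import MoleculeRecord

PAPER_SMILES: dict[str, str] = {
    "oseltamivir_carboxylate": "CCC(CC)O[C@@H]1C=C(C(=O)O)C[C@H](N)[C@@H]1NC(C)=O",
    "butan-2-one": "CCC(C)=O",
    "bromochlorofluoroiodomethane": "FC(Cl)(Br)I",
    "1-bromo-2-chloro-2-fluoro-1-iodoethene": "BrC(I)=C(Cl)F",
    "cis-1,4-di-tert-butylcyclohexane": "CC(C)(C)[C@H]1CC[C@H](CC1)C(C)(C)C",
    "propan-1-ol": "CCCO",
    "folic_acid": "Nc1nc2ncc(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1",
}


def paper_molecules() -> list[MoleculeRecord]:
    """The seven named exemplar molecules, as stable records."""
    return [
        MoleculeRecord(identifier=name, smiles=smiles, source_index=i)
        for i, (name, smiles) in enumerate(PAPER_SMILES.items())
    ]


def synthetic_library(
    n: int,
    seed: int = 0,
    frac_salts: float = 0.0,
    frac_ionizable: float = 0.0,
    frac_stereo: float = 0.0,
    frac_rings: float = 0.0,
) -> list[MoleculeRecord]:
    """Generate ``n`` valid, deterministic SMILES records.

    Each requested fraction is honored exactly: ``round(n * frac)`` records
    carry that feature (a counterion fragment, a carboxylic acid, an
    unspecified stereocenter, or a cyclohexane ring). Feature assignment is
    a seeded permutation, so the same (n, seed, fractions) always yields the
    same list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def pick(frac: float) -> set[int]:
        count = int(round(n * frac))
        if not 0 <= count <= n:
            raise ValueError(f"fraction {frac} out of range")
        return set(rng.permutation(n)[:count].tolist())

    with_salt = pick(frac_salts)
    with_ion = pick(frac_ionizable)
    with_stereo = pick(frac_stereo)
    with_ring = pick(frac_rings)

    records = []
    for i in range(n):
        chain = "C" * (2 + i % 4)
        smiles = chain + "OC"  # simple ether backbone, nothing enumerable
        if i in with_ring:
            smiles += "C1CCCCC1"
        if i in with_stereo:
            smiles = "FC(Cl)" + smiles  # CHFCl center, left unspecified
        if i in with_ion:
            smiles += "CC(=O)O"
        if i in with_salt:
            smiles += ".Cl"
        assert Chem.MolFromSmiles(smiles) is not None
        records.append(
            MoleculeRecord(identifier=f"synthetic_{i}", smiles=smiles, source_index=i)
        )
    return records


def write_fixture_files(directory: str | Path, records: list[MoleculeRecord]) -> tuple[Path, Path]:
    """Write records as both a .smi file and a flat .sdf for CLI-level tests."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    smi_path = directory / "fixtures.smi"
    smi_path.write_text(
        "".join(f"{r.smiles} {r.identifier}\n" for r in records)
    )
    sdf_path = directory / "fixtures.sdf"
    writer = Chem.SDWriter(str(sdf_path))
    try:
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles)
            if mol is None:
                continue
            AllChem.Compute2DCoords(mol)
            mol.SetProp("_Name", r.identifier)
            writer.write(mol)
    finally:
        writer.close()
    return smi_path, sdf_path
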