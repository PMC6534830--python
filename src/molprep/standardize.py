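"""Desalting: reduce multi-fragment inputs to the presumed compound of interest."""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem_model import ProvenanceStep, canonical_key


def desalt(mol: Chem.Mol) -> tuple[Chem.Mol, ProvenanceStep | None]:
    """Keep only the largest fragment of a (possibly multi-component) molecule.

    "Largest" means most heavy atoms; ties go to the larger molecular weight,
    then to the lexicographically smallest canonical key, so the result is
    deterministic.

    Returns the surviving fragment and a ``desalt`` provenance step when
    fragments were actually removed (``None`` for single-fragment input).
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot desalt an empty molecule")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol, None

    def sort_key(frag: Chem.Mol):
        return (-frag.GetNumHeavyAtoms(), -Descriptors.MolWt(frag), canonical_key(frag))

    ranked = sorted(frags, key=sort_key)
    kept = ranked[0]
    removed = [canonical_key(f) for f in ranked[1:]]
    step = ProvenanceStep("desalt", f"removed {len(removed)} fragment(s): {', '.join(removed)}")
    return kept, step
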