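"""Enumeration of unspecified tetrahedral and double-bond stereochemistry.

Only stereo elements the input leaves *unspecified* are varied; explicitly
assigned centers and bonds are never touched. Enumeration order is fixed
(centers by atom index, then bonds by bond index) so downstream seeded
sampling is reproducible.
"""

from __future__ import annotations

import itertools

from rdkit import Chem

from .chem_model import ProvenanceStep, Variant, canonical_key

#: double bonds inside rings smaller than this are geometrically forced cis
#: and are not enumerated
MIN_ENUMERABLE_RING_SIZE = 8


def _potential_stereo(mol: Chem.Mol):
    return Chem.FindPotentialStereo(mol)


def unspecified_chiral_atoms(mol: Chem.Mol) -> list[int]:
    """Atom indices of assignable-but-unassigned tetrahedral centers, sorted."""
    out = [
        int(info.centeredOn)
        for info in _potential_stereo(mol)
        if info.type == Chem.StereoType.Atom_Tetrahedral
        and info.specified == Chem.StereoSpecified.Unspecified
    ]
    return sorted(out)


def unspecified_double_bonds(mol: Chem.Mol) -> list[int]:
    """Bond indices of unspecified stereogenic double bonds, sorted.

    Bonds inside rings of fewer than ``MIN_ENUMERABLE_RING_SIZE`` atoms are
    skipped: their geometry is forced.
    """
    ri = mol.GetRingInfo()
    out = []
    for info in _potential_stereo(mol):
        if info.type != Chem.StereoType.Bond_Double:
            continue
        if info.specified != Chem.StereoSpecified.Unspecified:
            continue
        bond_idx = int(info.centeredOn)
        if ri.NumBondRings(bond_idx) and ri.MinBondRingSize(bond_idx) < MIN_ENUMERABLE_RING_SIZE:
            continue
        out.append(bond_idx)
    return sorted(out)


def _normalize(mol: Chem.Mol) -> Chem.Mol | None:
    """Round-trip through canonical SMILES so stereo flags are canonicalized."""
    smi = Chem.MolToSmiles(mol)
    return Chem.MolFromSmiles(smi)


def enumerate_chiral(
    mol: Chem.Mol, parent: Variant | None = None
) -> list[Variant]:
    """Cartesian product of R/S over the unspecified tetrahedral centers.

    Duplicates arising from meso symmetry collapse via canonical keys. Input
    with no unspecified centers passes through as a single unchanged variant.
    """
    base = parent if parent is not None else Variant(parent_id="", mol=mol)
    centers = unspecified_chiral_atoms(mol)
    if not centers:
        return [base.copy()]

    tags = (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    variants: list[Variant] = []
    seen: set[str] = set()
    for combo in itertools.product(tags, repeat=len(centers)):
        rw = Chem.RWMol(mol)
        for atom_idx, tag in zip(centers, combo):
            rw.GetAtomWithIdx(atom_idx).SetChiralTag(tag)
        candidate = _normalize(rw.GetMol())
        if candidate is None:
            continue
        key = canonical_key(candidate)
        if key in seen:
            continue
        seen.add(key)
        detail = "; ".join(
            f"atom {a} -> {'CW' if t == tags[0] else 'CCW'}"
            for a, t in zip(centers, combo)
        )
        variants.append(base.child(candidate, ProvenanceStep("chirality", detail)))
    return variants if variants else [base.copy()]


def enumerate_cis_trans(
    mol: Chem.Mol, parent: Variant | None = None
) -> list[Variant]:
    """Cartesian product of cis/trans over unspecified stereogenic double bonds."""
    base = parent if parent is not None else Variant(parent_id="", mol=mol)
    bonds = unspecified_double_bonds(mol)
    if not bonds:
        return [base.copy()]

    stereo_infos = {
        int(info.centeredOn): info
        for info in _potential_stereo(mol)
        if info.type == Chem.StereoType.Bond_Double
    }
    settings = (Chem.BondStereo.STEREOCIS, Chem.BondStereo.STEREOTRANS)
    variants: list[Variant] = []
    seen: set[str] = set()
    for combo in itertools.product(settings, repeat=len(bonds)):
        rw = Chem.RWMol(mol)
        ok = True
        for bond_idx, stereo in zip(bonds, combo):
            info = stereo_infos[bond_idx]
            n_atoms = rw.GetNumAtoms()
            # missing controlling atoms are encoded as NOATOM (unsigned -1)
            ctrl = [int(a) for a in info.controllingAtoms]
            if len(ctrl) < 3 or not (0 <= ctrl[0] < n_atoms and 0 <= ctrl[2] < n_atoms):
                ok = False
                break
            bond = rw.GetBondWithIdx(bond_idx)
            bond.SetStereoAtoms(int(ctrl[0]), int(ctrl[2]))
            bond.SetStereo(stereo)
        if not ok:
            continue
        candidate = _normalize(rw.GetMol())
        if candidate is None:
            continue
        key = canonical_key(candidate)
        if key in seen:
            continue
        seen.add(key)
        detail = "; ".join(
            f"bond {b} -> {'cis' if s == settings[0] else 'trans'}"
            for b, s in zip(bonds, combo)
        )
        variants.append(base.child(candidate, ProvenanceStep("cis_trans", detail)))
    return variants if variants else [base.copy()]
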