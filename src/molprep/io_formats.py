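"""Readers and writers for the supported interchange formats.

Input: SMILES line files (one ``SMILES [name]`` per line) and flat V2000 SDF
(any coordinates present are ignored). Output: SDF with provenance data
fields, optionally PDB (one file per variant) and a self-contained HTML
gallery of 2D depictions.

Unparseable lines/blocks become failed records rather than aborting, so a
single bad entry never kills a library run.
"""

from __future__ import annotations

import html as html_mod
import warnings
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Draw import rdMolDraw2D

from .chem_model import MoleculeRecord, Variant

#: SDF data-field names used for provenance
FIELD_GENEALOGY = "Genealogy"
FIELD_PARENT = "Parent"
FIELD_VARIANT_INDEX = "VariantIndex"


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Parse a SMILES line file into molecule records.

    Fields are whitespace-separated: the first token is the SMILES, the rest
    of the line is the name. Nameless records get ``mol_<line index>``.
    Blank lines and ``#`` comments are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    index = 0
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"mol_{index}"
        record = MoleculeRecord(identifier=name, smiles=smiles, source_index=index)
        if Chem.MolFromSmiles(smiles) is None:
            record.failed = True
            record.failure_reason = f"unparseable SMILES: {smiles!r}"
        records.append(record)
        index += 1
    if not records:
        warnings.warn(f"no molecule records found in {path}")
    return records


def read_sdf_flat(path: str | Path) -> list[MoleculeRecord]:
    """Parse a flat (2D / no-coordinate) V2000 SDF into molecule records.

    3D coordinates, if present, are discarded: only the connection table is
    kept. Blocks RDKit cannot parse become failed records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    records: list[MoleculeRecord] = []
    for index, mol in enumerate(supplier):
        if mol is None:
            records.append(
                MoleculeRecord(
                    identifier=f"mol_{index}",
                    smiles="",
                    source_index=index,
                    failed=True,
                    failure_reason="unparseable SDF block",
                )
            )
            continue
        name = (mol.GetProp("_Name") if mol.HasProp("_Name") else "").strip()
        records.append(
            MoleculeRecord(
                identifier=name or f"mol_{index}",
                smiles=Chem.MolToSmiles(mol),
                source_index=index,
            )
        )
    if not records:
        warnings.warn(f"no molecule records found in {path}")
    return records


def _writable_mol(variant: Variant, variant_index: int) -> Chem.Mol:
    if variant.conformer is None or variant.mol3d is None:
        raise ValueError(
            f"variant {variant_index} of {variant.parent_id!r} has no 3D coordinates"
        )
    mol = Chem.Mol(variant.mol3d)
    mol.SetProp("_Name", f"{variant.parent_id}__{variant_index}")
    mol.SetProp(FIELD_PARENT, variant.parent_id)
    mol.SetProp(FIELD_VARIANT_INDEX, str(variant_index))
    mol.SetProp(FIELD_GENEALOGY, "; ".join(str(s) for s in variant.provenance))
    if variant.energy is not None:
        mol.SetProp("Energy", f"{variant.energy:.4f}")
    return mol


def write_sdf(variants: list[Variant], path: str | Path) -> None:
    """Write variants to a V2000 SDF with provenance data fields."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for i, variant in enumerate(variants):
            writer.write(_writable_mol(variant, i))
    finally:
        writer.close()


def write_pdb(variants: list[Variant], directory: str | Path) -> list[Path]:
    """One PDB file per variant; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, variant in enumerate(variants):
        mol = _writable_mol(variant, i)
        safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in variant.parent_id)
        out = directory / f"{safe}__{i}.pdb"
        Chem.MolToPDBFile(mol, str(out))
        paths.append(out)
    return paths


def write_html(variants: list[Variant], path: str | Path) -> None:
    """Self-contained HTML gallery: one 2D depiction + caption per variant."""
    path = Path(path)
    entries = []
    for i, variant in enumerate(variants):
        if variant.conformer is None:
            raise ValueError(f"variant {i} of {variant.parent_id!r} has no 3D coordinates")
        flat = Chem.Mol(variant.mol)
        AllChem.Compute2DCoords(flat)
        drawer = rdMolDraw2D.MolDraw2DSVG(240, 200)
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, flat)
        drawer.FinishDrawing()
        svg = drawer.GetDrawingText()
        caption = html_mod.escape(
            f"{variant.parent_id} [{i}] — " + "; ".join(str(s) for s in variant.provenance)
        )
        entries.append(
            f'<div class="variant">{svg}<p>{caption}</p></div>'
        )
    body = "\n".join(entries)
    path.write_text(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<style>.variant{display:inline-block;margin:8px;border:1px solid #ccc;"
        "padding:4px;max-width:260px;font:12px sans-serif}</style>"
        f"</head><body>{body}</body></html>"
    )
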