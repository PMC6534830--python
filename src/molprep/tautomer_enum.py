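"""Tautomer enumeration and filtering of improbable forms.

Enumeration is delegated to RDKit's rule-based tautomer enumerator (the
lineage of the MolVS transform set: 1,3-keto/enol, imine/enamine,
amide/iminol, nitroso/oxime, aromatic-heterocycle proton shifts, ...).
The input form is always part of the returned set.

Filtering then rejects candidates that

* change the number of aromatic rings (break existing aromaticity),
* change the number of (assigned + assignable) chiral centers,
* contain an enol whose alkene is terminal,
* contain a geminal vinyl diol (an improbable carboxylic-acid tautomer), or
* contain a carbanion.

Note that the enumerator strips cis/trans assignments from double bonds
whose order changes in any tautomeric form; such bonds are deliberately left
unspecified here and re-enumerated by the downstream stereo stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem_model import (
    ProvenanceStep,
    Variant,
    canonical_key,
    count_aromatic_rings,
    count_chiral_centers,
)

DEFAULT_MAX_TAUTOMERS = 64


@dataclass(frozen=True)
class BlacklistPattern:
    name: str
    smarts: str

    @property
    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for blacklist entry {self.name!r}")
        return patt


def load_blacklist(path: str | None = None) -> list[BlacklistPattern]:
    """Packaged improbable-tautomer substructure list (user-overridable)."""
    if path is None:
        raw = resources.files("molprep.data").joinpath("tautomer_blacklist.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    data = json.loads(raw)
    return [BlacklistPattern(e["name"], e["smarts"]) for e in data["patterns"]]


_BLACKLIST: list[BlacklistPattern] | None = None


def default_blacklist() -> list[BlacklistPattern]:
    global _BLACKLIST
    if _BLACKLIST is None:
        _BLACKLIST = load_blacklist()
    return _BLACKLIST


def enumerate_tautomers(
    mol: Chem.Mol, max_tautomers: int = DEFAULT_MAX_TAUTOMERS
) -> list[Chem.Mol]:
    """All rule-derivable tautomers of ``mol`` (capped), input included."""
    enumerator = rdMolStandardize.TautomerEnumerator()
    enumerator.SetMaxTautomers(max_tautomers)
    try:
        results = list(enumerator.Enumerate(mol))
    except Exception:
        results = []
    key_self = canonical_key(mol)
    out = [mol]
    seen = {key_self}
    for taut in results:
        key = canonical_key(taut)
        if key not in seen:
            seen.add(key)
            out.append(taut)
    return out


def matches_blacklist(
    mol: Chem.Mol, blacklist: list[BlacklistPattern] | None = None
) -> str | None:
    """Name of the first blacklist pattern found in ``mol``, else ``None``."""
    if blacklist is None:
        blacklist = default_blacklist()
    for entry in blacklist:
        if mol.HasSubstructMatch(entry.pattern):
            return entry.name
    return None


def filter_tautomers(
    candidates: list[Chem.Mol],
    parent: Chem.Mol,
    parent_variant: Variant | None = None,
    blacklist: list[BlacklistPattern] | None = None,
) -> list[Variant]:
    """Apply the improbable-tautomer filters against a parent molecule.

    If every candidate is rejected the parent form itself is retained, so the
    stage never empties a molecule's variant set.
    """
    base = parent_variant if parent_variant is not None else Variant(parent_id="", mol=parent)
    n_aromatic = count_aromatic_rings(parent)
    n_chiral = count_chiral_centers(parent)
    parent_key = canonical_key(parent)

    kept: list[Variant] = []
    seen: set[str] = set()
    for cand in candidates:
        key = canonical_key(cand)
        if key in seen:
            continue
        if count_aromatic_rings(cand) != n_aromatic:
            continue
        if count_chiral_centers(cand) != n_chiral:
            continue
        if matches_blacklist(cand, blacklist) is not None:
            continue
        seen.add(key)
        detail = "input form" if key == parent_key else f"tautomer of {parent_key}"
        kept.append(base.child(cand, ProvenanceStep("tautomerize", detail)))
    if not kept:
        kept = [base.child(parent, ProvenanceStep("tautomerize", "all tautomers rejected; kept input"))]
    return kept
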