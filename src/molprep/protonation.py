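"""Ionization-state enumeration over a pH window, with charge pruning.

Each entry of a curated substructure/pKa table identifies one titratable
atom. For a window [min_ph, max_ph] and a precision p, a site is considered

* deprotonated when ``pKa - p < max_ph``,
* protonated  when ``pKa + p > min_ph``,

and both forms are emitted when both hold. The Cartesian product of the
allowed states over all sites yields the candidate ionization forms, which
are deduplicated by canonical key.

Highly charged forms are pruned relative to the form whose net charge is
closest to zero: any form differing from that baseline by 3 e or more is
eliminated.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources

from rdkit import Chem

from .chem_model import ProvenanceStep, Variant, canonical_key, net_formal_charge


@dataclass(frozen=True)
class IonizableSite:
    """One titratable substructure class from the site table."""

    name: str
    smarts: str
    site: int  # index of the titratable atom within the SMARTS match
    mean_pka: float
    spread: float
    deprotonated_charge: int
    protonated_charge: int

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("pKa spread must be non-negative")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise ValueError(f"invalid SMARTS for site {self.name!r}")

    @property
    def pattern(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)


def load_site_table(path: str | None = None) -> list[IonizableSite]:
    """Load the packaged site/pKa table, or a user-supplied JSON file."""
    if path is None:
        raw = resources.files("molprep.data").joinpath("ionizable_sites.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    data = json.loads(raw)
    return [
        IonizableSite(
            name=e["name"],
            smarts=e["smarts"],
            site=e["site"],
            mean_pka=e["mean_pka"],
            spread=e["spread"],
            deprotonated_charge=e["deprotonated_charge"],
            protonated_charge=e["protonated_charge"],
        )
        for e in data["sites"]
    ]


_DEFAULT_TABLE: list[IonizableSite] | None = None


def default_site_table() -> list[IonizableSite]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_site_table()
    return _DEFAULT_TABLE


def find_ionizable_sites(
    mol: Chem.Mol, table: list[IonizableSite] | None = None
) -> list[tuple[int, IonizableSite]]:
    """Match the table against a molecule.

    Returns (atom index, table entry) pairs; each atom is claimed by at most
    one entry, earlier table entries taking priority.
    """
    if table is None:
        table = default_site_table()
    claimed: set[int] = set()
    sites: list[tuple[int, IonizableSite]] = []
    for entry in table:
        for match in mol.GetSubstructMatches(entry.pattern):
            atom_idx = match[entry.site]
            if atom_idx in claimed:
                continue
            claimed.add(atom_idx)
            sites.append((atom_idx, entry))
    return sites


def allowed_states(
    entry: IonizableSite, min_ph: float, max_ph: float, pka_precision: float
) -> list[str]:
    """Which of {'deprotonated', 'protonated'} the window admits for a site.

    Never empty: the two conditions cannot both fail when min_ph <= max_ph.
    """
    states = []
    if entry.mean_pka - pka_precision < max_ph:
        states.append("deprotonated")
    if entry.mean_pka + pka_precision > min_ph:
        states.append("protonated")
    return states


def _set_site_state(rwmol: Chem.RWMol, atom_idx: int, entry: IonizableSite, state: str) -> None:
    atom = rwmol.GetAtomWithIdx(atom_idx)
    total_h = atom.GetTotalNumHs()
    currently_protonated = atom.GetFormalCharge() == entry.protonated_charge
    if state == "deprotonated":
        atom.SetFormalCharge(entry.deprotonated_charge)
        if currently_protonated:
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(max(0, total_h - 1))
    else:
        atom.SetFormalCharge(entry.protonated_charge)
        if not currently_protonated:
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(total_h + 1)


def enumerate_ionization_states(
    mol: Chem.Mol,
    min_ph: float = 6.4,
    max_ph: float = 8.4,
    pka_precision: float = 1.0,
    table: list[IonizableSite] | None = None,
    parent: Variant | None = None,
    max_combinations: int = 256,
) -> list[Variant]:
    """Enumerate ionization forms of ``mol`` over the pH window.

    Returns one Variant per distinct form, each carrying an ``ionize``
    provenance step. A molecule with no matched sites is returned unchanged
    as its own single variant.
    """
    if min_ph > max_ph:
        raise ValueError("min_ph must not exceed max_ph")
    if pka_precision < 0:
        raise ValueError("pka_precision must be non-negative")

    base = parent if parent is not None else Variant(parent_id="", mol=mol)
    sites = find_ionizable_sites(mol, table)
    if not sites:
        out = base.child(mol, ProvenanceStep("ionize", "no ionizable sites"))
        return [out]

    per_site = [
        allowed_states(entry, min_ph, max_ph, pka_precision) for _, entry in sites
    ]

    variants: list[Variant] = []
    seen: set[str] = set()
    for combo in itertools.islice(itertools.product(*per_site), max_combinations):
        rw = Chem.RWMol(mol)
        for (atom_idx, entry), state in zip(sites, combo):
            _set_site_state(rw, atom_idx, entry, state)
        candidate = rw.GetMol()
        try:
            Chem.SanitizeMol(candidate)
        except Exception:
            continue
        key = canonical_key(candidate)
        if key in seen:
            continue
        seen.add(key)
        detail = "; ".join(
            f"{entry.name}@{atom_idx} {state}"
            for (atom_idx, entry), state in zip(sites, combo)
        )
        variants.append(base.child(candidate, ProvenanceStep("ionize", detail)))
    if not variants:  # every combination failed sanitization
        variants = [base.child(mol, ProvenanceStep("ionize", "all forms unsanitizable; kept input"))]
    return variants


def prune_by_formal_charge(variants: list[Variant]) -> list[Variant]:
    """Drop ionization forms whose net charge deviates from the baseline by >= 3 e.

    The baseline is the net charge of the variant closest to zero; when +q
    and -q are equally close, the more negative candidate is the baseline.
    """
    if not variants:
        raise ValueError("prune_by_formal_charge requires a non-empty variant list")
    charges = [net_formal_charge(v.mol) for v in variants]
    baseline = min(charges, key=lambda q: (abs(q), q))
    return [v for v, q in zip(variants, charges) if abs(q - baseline) <= 2]
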