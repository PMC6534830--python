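"""Alternate conformations of non-aromatic rings.

Multiple 3D models of a molecule are embedded and force-field optimized.
Each model's non-aromatic ring geometries are summarized into a fingerprint:
for ring r of model m, the entry is the minimum RMSD between that ring's
coordinates and the same ring's coordinates in model 1, minimized over rigid
rotation and translation (closed-form Kabsch superposition). The first
model's fingerprint is therefore the zero vector. Fingerprints are clustered
with k-means and only the model closest to each cluster centroid (the
medoid) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from sklearn.cluster import KMeans

from .chem_model import Conformer3D
from .geometry import DEFAULT_BACKEND, EmbedError, conformer_coordinates

KMEANS_RESTARTS = 10


@dataclass
class RingGeometry:
    """Ordered coordinates of one ring's atoms in one model."""

    ring_index: int
    coordinates: np.ndarray  # (A_r, 3)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.coordinates) < 3:
            raise ValueError("a ring needs at least 3 atoms")


@dataclass
class ModelRingState:
    """All ring geometries of one 3D model."""

    model_index: int
    rings: list[RingGeometry]


def extract_nonaromatic_rings(mol: Chem.Mol) -> list[list[int]]:
    """Ordered atom-index lists of the non-aromatic SSSR rings.

    The ordering of atoms within each ring, and of rings within the list, is
    RDKit's ring-perception order — identical for every conformer of the
    same molecule, which is all the fingerprint construction requires.
    """
    ri = mol.GetRingInfo()
    out = []
    for atom_ring, bond_ring in zip(ri.AtomRings(), ri.BondRings()):
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ring):
            continue
        out.append(list(atom_ring))
    return out


def superposition_rmsd(c1: np.ndarray, c2: np.ndarray) -> float:
    """Minimum RMSD between two corresponded point sets under rigid motion.

    Kabsch closed form: translate both sets to their centroids, rotate c1
    onto c2 with the SVD-derived optimal (proper) rotation, and measure the
    residual RMSD. Atom correspondence is positional (i-th to i-th).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError(f"coordinate shapes differ: {c1.shape} vs {c2.shape}")
    if len(c1) < 3:
        raise ValueError("superposition needs at least 3 points")

    x = c1 - c1.mean(axis=0)
    y = c2 - c2.mean(axis=0)
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    diff = (rot @ x.T).T - y
    return float(np.sqrt((diff**2).sum() / len(c1)))


def ring_states(
    mol3d: Chem.Mol, ring_atom_lists: list[list[int]]
) -> list[ModelRingState]:
    """Collect per-model ring geometries for every conformer of ``mol3d``."""
    states = []
    for m, conf in enumerate(mol3d.GetConformers(), start=1):
        pos = np.array(conf.GetPositions(), dtype=float)
        rings = [
            RingGeometry(r, pos[atoms]) for r, atoms in enumerate(ring_atom_lists, start=1)
        ]
        states.append(ModelRingState(m, rings))
    return states


def ring_fingerprints(models: list[ModelRingState]) -> np.ndarray:
    """(M, R) matrix of per-ring superposition RMSDs against model 1."""
    if not models:
        return np.zeros((0, 0))
    reference = models[0]
    n_rings = len(reference.rings)
    fps = np.zeros((len(models), n_rings))
    for i, model in enumerate(models):
        if len(model.rings) != n_rings:
            raise ValueError("models disagree on ring definitions")
        for r in range(n_rings):
            fps[i, r] = superposition_rmsd(
                model.rings[r].coordinates, reference.rings[r].coordinates
            )
    return fps


def select_ring_medoids(
    fingerprints: np.ndarray, k_max: int, seed: int = 0
) -> list[int]:
    """Cluster fingerprints with k-means; return one medoid index per cluster.

    k = min(k_max, number of distinct fingerprints). The medoid of a cluster
    is its member nearest the centroid; ties go to the lowest model index.
    Returned indices are 0-based positions into ``fingerprints``, sorted.
    """
    fps = np.asarray(fingerprints, dtype=float)
    if fps.ndim == 1:
        fps = fps.reshape(-1, 1)
    if len(fps) == 0:
        raise ValueError("no fingerprints to cluster")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    distinct = np.unique(fps.round(decimals=8), axis=0)
    k = min(k_max, len(distinct))
    if k == len(fps):
        return list(range(len(fps)))

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=KMEANS_RESTARTS,
        random_state=seed % (2**32),
    )
    labels = km.fit_predict(fps)
    medoids = []
    for cluster in range(k):
        members = np.flatnonzero(labels == cluster)
        if len(members) == 0:
            continue
        dists = np.linalg.norm(fps[members] - km.cluster_centers_[cluster], axis=1)
        medoids.append(int(members[np.argmin(dists)]))  # argmin is first = lowest index
    return sorted(set(medoids))


def embed_models(
    mol: Chem.Mol, n_models: int, seed: int, backend=None
) -> tuple[Chem.Mol, list[Conformer3D]]:
    """Embed and optimize ``n_models`` 3D models of a molecule.

    Returns the hydrogen-explicit molecule carrying all conformers plus one
    ``Conformer3D`` per model (optimized coordinates and energies). Raises
    ``EmbedError`` when the molecule cannot be embedded at all.
    """
    backend = backend or DEFAULT_BACKEND
    mol3d = backend.embed_multiple(mol, n_models, seed)
    conformers = []
    for conf in mol3d.GetConformers():
        energy = backend.optimize(mol3d, conf.GetId())
        conformers.append(
            Conformer3D(
                coordinates=conformer_coordinates(mol3d, conf.GetId()),
                energy=energy,
                optimized=True,
            )
        )
    return mol3d, conformers


def select_ring_conformers(
    mol: Chem.Mol, n_models: int, k_max: int, seed: int, backend=None
) -> tuple[Chem.Mol, list[int], list[Conformer3D]]:
    """Full ring-conformer stage for one molecule.

    Embeds ``n_models`` models, fingerprints their non-aromatic rings, and
    returns the hydrogen-explicit molecule, the retained (medoid) conformer
    positions, and all per-model conformers.
    """
    rings = extract_nonaromatic_rings(mol)
    if not rings:
        raise ValueError("molecule has no non-aromatic rings; stage does not apply")
    mol3d, conformers = embed_models(mol, n_models, seed, backend=backend)
    # ring atom indices are unchanged by AddHs (hydrogens are appended)
    states = ring_states(mol3d, rings)
    fps = ring_fingerprints(states)
    medoids = select_ring_medoids(fps, k_max, seed=seed)
    return mol3d, medoids, conformers


# --- six-membered-ring shape diagnostics (used by tests and reports) -----


def ring_torsions(coords: np.ndarray) -> np.ndarray:
    """Endocyclic torsion angles (degrees) around an ordered ring."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    out = np.empty(n)
    for i in range(n):
        p0, p1, p2, p3 = (coords[(i + j) % n] for j in range(4))
        b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m1 = np.cross(n1, b1 / np.linalg.norm(b1))
        x = np.dot(n1, n2)
        y = np.dot(m1, n2)
        out[i] = np.degrees(np.arctan2(y, x))
    return out


def classify_six_ring(coords: np.ndarray) -> str:
    """'chair', 'twist_boat', 'boat', or 'other' from endocyclic torsions."""
    tors = ring_torsions(coords)
    if len(tors) != 6:
        raise ValueError("classification defined for six-membered rings only")
    mags = np.abs(tors)
    signs = np.sign(tors)
    alternating = all(signs[i] * signs[(i + 1) % 6] < 0 for i in range(6))
    if alternating and np.all((mags > 40) & (mags < 70)):
        return "chair"
    if np.any(mags < 12) and np.all(mags < 80):
        return "boat"
    if not alternating and np.all((mags > 12) & (mags < 80)):
        return "twist_boat"
    return "other"


def substituent_is_equatorial(
    ring_coords: np.ndarray, ring_atom_pos: np.ndarray, substituent_pos: np.ndarray
) -> bool:
    """Equatorial when the exocyclic bond lies closer to the mean ring plane
    than to its normal (angle to the normal > 45 degrees)."""
    ring_coords = np.asarray(ring_coords, dtype=float)
    center = ring_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(ring_coords - center)
    normal = vt[2]
    bond = np.asarray(substituent_pos) - np.asarray(ring_atom_pos)
    bond = bond / np.linalg.norm(bond)
    cos_angle = abs(float(np.dot(bond, normal)))
    return cos_angle < np.cos(np.radians(45))
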