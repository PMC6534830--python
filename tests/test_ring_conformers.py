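import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molprep.chem_model import mol_from_smiles
from molprep.geometry import conformer_coordinates
from molprep.ring_conformers import (
    ModelRingState,
    RingGeometry,
    classify_six_ring,
    embed_models,
    extract_nonaromatic_rings,
    ring_fingerprints,
    ring_states,
    select_ring_medoids,
    superposition_rmsd,
)
from oracles import exhaustive_medoids, rmsd_rotation_grid


class TestSuperpositionRMSD:
    def test_identical_zero(self):
        pts = np.arange(12, dtype=float).reshape(4, 3)
        assert superposition_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_zero(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(6, 3))
            rot = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            moved = pts @ rot.T + rng.normal(size=3)
            assert superposition_rmsd(pts, moved) < 1e-6

    def test_symmetry(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert superposition_rmsd(a, b) == pytest.approx(superposition_rmsd(b, a), abs=1e-9)

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError):
            superposition_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_square_vs_rectangle_frozen_oracle_value(self):
        # frozen from the rotation-grid oracle: exactly 0.5 A
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        rect = np.array([[0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1, 0]], float)
        assert superposition_rmsd(square, rect) == pytest.approx(0.5, abs=1e-9)

    def test_matches_grid_oracle_random_sets(self, rng):
        for _ in range(4):
            n = int(rng.integers(3, 9))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            assert superposition_rmsd(a, b) == pytest.approx(
                rmsd_rotation_grid(a, b), abs=1e-3
            )

    def test_triangle_inequality(self, rng):
        for _ in range(10):
            a, b, c = (rng.normal(size=(5, 3)) for _ in range(3))
            ab = superposition_rmsd(a, b)
            bc = superposition_rmsd(b, c)
            ac = superposition_rmsd(a, c)
            assert ac <= ab + bc + 1e-9


class TestRingExtraction:
    def test_benzene_excluded(self):
        assert extract_nonaromatic_rings(mol_from_smiles("c1ccccc1")) == []

    def test_cyclohexane(self):
        rings = extract_nonaromatic_rings(mol_from_smiles("C1CCCCC1"))
        assert len(rings) == 1 and len(rings[0]) == 6

    def test_tetralin_one_nonaromatic(self):
        rings = extract_nonaromatic_rings(mol_from_smiles("c1ccc2c(c1)CCCC2"))
        assert len(rings) == 1 and len(rings[0]) == 6

    def test_acyclic_none(self):
        assert extract_nonaromatic_rings(mol_from_smiles("CCCCC")) == []


class TestFingerprints:
    def _states(self, coords_per_model):
        return [
            ModelRingState(m + 1, [RingGeometry(1, coords)])
            for m, coords in enumerate(coords_per_model)
        ]

    def test_single_model_zero_vector(self, rng):
        fps = ring_fingerprints(self._states([rng.normal(size=(6, 3))]))
        assert fps.shape == (1, 1)
        assert np.allclose(fps, 0)

    def test_first_fingerprint_always_zero(self, rng):
        models = self._states([rng.normal(size=(6, 3)) for _ in range(5)])
        fps = ring_fingerprints(models)
        assert np.allclose(fps[0], 0)

    def test_rigid_copies_all_zero(self, rng):
        base = rng.normal(size=(6, 3))
        models = [base]
        for _ in range(3):
            rot = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            models.append(base @ rot.T + rng.normal(size=3))
        fps = ring_fingerprints(self._states(models))
        assert np.allclose(fps, 0, atol=1e-6)


class TestMedoidSelection:
    def test_all_identical_one_cluster(self):
        fps = np.zeros((8, 2))
        assert select_ring_medoids(fps, k_max=5) == [0]

    def test_fewer_distinct_than_budget_keeps_all(self):
        fps = np.array([[0.0], [1.0], [2.0]])
        assert select_ring_medoids(fps, k_max=5) == [0, 1, 2]

    def test_three_blobs_match_exhaustive_oracle(self, rng):
        centers = [0.0, 5.0, 10.0]
        pts = np.concatenate([c + 0.01 * rng.normal(size=4) for c in centers]).reshape(-1, 1)
        got = select_ring_medoids(pts, k_max=3, seed=11)
        expected = exhaustive_medoids(pts, 3)
        assert got == expected
        # one medoid per blob, each within its own blob
        assert [m // 4 for m in got] == [0, 1, 2]

    def test_random_separated_sets_match_oracle(self, rng):
        for trial in range(3):
            k = 2 + trial % 2
            pts = np.concatenate(
                [10.0 * j + 0.05 * rng.normal(size=(3, 2)) for j in range(k)]
            )
            assert select_ring_medoids(pts, k_max=k, seed=trial) == exhaustive_medoids(pts, k)

    def test_budget_respected(self, rng):
        fps = rng.normal(size=(20, 3))
        assert len(select_ring_medoids(fps, k_max=5, seed=0)) <= 5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_ring_medoids(np.zeros((0, 1)), k_max=3)


class TestEmbedding:
    def test_ethane_three_models(self):
        _, conformers = embed_models(mol_from_smiles("CC"), 3, seed=4)
        assert len(conformers) == 3
        assert all(np.isfinite(c.energy) for c in conformers)
        assert all(c.optimized for c in conformers)

    def test_determinism(self):
        mol = mol_from_smiles("CCCC")
        m1, _ = embed_models(mol, 2, seed=9)
        m2, _ = embed_models(mol, 2, seed=9)
        for cid in range(2):
            assert np.allclose(
                conformer_coordinates(m1, cid), conformer_coordinates(m2, cid)
            )

    def test_cyclohexane_chairs_dominate(self):
        mol = mol_from_smiles("C1CCCCC1")
        mol3d, _ = embed_models(mol, 10, seed=3)
        rings = extract_nonaromatic_rings(mol)
        states = ring_states(mol3d, rings)
        labels = [classify_six_ring(s.rings[0].coordinates) for s in states]
        assert labels.count("chair") >= 5  # chair is the UFF minimum

    def test_bridged_failure_raises_embed_error(self, stub_backend):
        from molprep.geometry import EmbedError

        stub_backend.fail_keys = {"C1CCCCC1"}
        with pytest.raises(EmbedError):
            embed_models(mol_from_smiles("C1CCCCC1"), 2, seed=0, backend=stub_backend)
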