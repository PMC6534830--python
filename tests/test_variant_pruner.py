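import math

import numpy as np
import pytest
from scipy.stats import chi2

from molprep.chem_model import canonical_key
from molprep.geometry import EmbedError
from molprep.variant_pruner import (
    finalize_variants,
    full_enumeration_count,
    prune_variants,
    stage_rng,
    stage_seed,
)

from conftest import StubBackend, make_variants


def chain_variants(n):
    return make_variants(["C" * k for k in range(1, n + 1)])


class TestPruneVariants:
    def test_under_budget_untouched(self, stub_backend):
        variants = chain_variants(3)
        out = prune_variants(variants, m=5, t=3, rng=np.random.default_rng(0), backend=stub_backend)
        assert out == variants
        assert stub_backend.embed_calls == []  # no embedding below the budget

    def test_default_budget_15_sampled_5_kept(self, stub_backend):
        variants = chain_variants(32)
        out = prune_variants(variants, m=5, t=3, rng=np.random.default_rng(1), backend=stub_backend)
        assert len(stub_backend.embed_calls) == 15
        assert len(out) == 5

    def test_lowest_energies_retained(self):
        variants = chain_variants(15)
        energies = {canonical_key(v.mol): float(i + 1) for i, v in enumerate(variants)}
        backend = StubBackend(energy_fn=energies)
        out = prune_variants(variants, m=5, t=3, rng=np.random.default_rng(2), backend=backend)
        # all 15 sampled (m*t == population), so exactly energies 1..5 survive
        assert sorted(v.energy for v in out) == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_energy_tie_broken_by_canonical_key(self):
        variants = chain_variants(10)
        backend = StubBackend(default_energy=7.0)
        out = prune_variants(variants, m=3, t=4, rng=np.random.default_rng(3), backend=backend)
        keys = [canonical_key(v.mol) for v in out]
        assert keys == sorted(keys)

    def test_deterministic_under_seed(self, stub_backend):
        variants = chain_variants(20)
        a = prune_variants(variants, 5, 2, rng=np.random.default_rng(7), backend=StubBackend())
        b = prune_variants(variants, 5, 2, rng=np.random.default_rng(7), backend=StubBackend())
        assert [v.key() for v in a] == [v.key() for v in b]

    def test_embedding_failures_dropped(self):
        variants = chain_variants(8)
        bad = {canonical_key(variants[0].mol), canonical_key(variants[1].mol)}
        backend = StubBackend(fail_keys=bad)
        out = prune_variants(variants, m=2, t=4, rng=np.random.default_rng(4), backend=backend)
        assert len(out) == 2
        assert all(canonical_key(v.mol) not in bad for v in out)

    def test_all_failures_raise(self):
        variants = chain_variants(4)
        backend = StubBackend(fail_keys={canonical_key(v.mol) for v in variants})
        with pytest.raises(EmbedError):
            prune_variants(variants, m=1, t=4, rng=np.random.default_rng(5), backend=backend)

    def test_sampling_uniform_chi_square(self):
        # with a constant-energy backend, which variants get embedded is a
        # uniform m*t-subset; check per-variant inclusion frequencies
        variants = chain_variants(10)
        n_runs, m, t = 200, 2, 3
        counts = {v.key(): 0 for v in variants}
        for run in range(n_runs):
            backend = StubBackend()
            prune_variants(variants, m, t, rng=np.random.default_rng(run), backend=backend)
            for key in backend.embed_calls:
                counts[key] += 1
        expected = n_runs * (m * t) / len(variants)
        stat = sum((obs - expected) ** 2 / expected for obs in counts.values())
        assert stat < chi2.ppf(0.999, df=len(variants) - 1)

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            prune_variants(chain_variants(2), m=0, t=1, rng=np.random.default_rng(0))


class TestFinalize:
    def test_optimized_passthrough_bitwise(self, stub_backend):
        variants = chain_variants(3)
        pruned = prune_variants(variants, 2, 2, rng=np.random.default_rng(0), backend=stub_backend)
        # mark as already optimized; coordinates must come back untouched
        for v in variants:
            v.mol3d = stub_backend.embed(v.mol, 0)
            from molprep.chem_model import Conformer3D
            from molprep.geometry import conformer_coordinates

            v.conformer = Conformer3D(conformer_coordinates(v.mol3d), energy=1.0, optimized=True)
        before = [v.conformer.coordinates.copy() for v in variants]
        out = finalize_variants(variants, backend=stub_backend)
        assert stub_backend.optimize_calls == []
        for v, coords in zip(out, before):
            assert np.array_equal(v.conformer.coordinates, coords)

    def test_unoptimized_gets_optimized(self):
        backend = StubBackend(default_energy=5.0)
        variants = chain_variants(2)
        pruned = prune_variants(variants, 1, 2, rng=np.random.default_rng(0), backend=backend)
        assert pruned[0].conformer.optimized is False
        pre = pruned[0].energy
        out = finalize_variants(pruned, backend=backend)
        assert out[0].conformer.optimized is True
        assert out[0].energy <= pre  # minimizer contract

    def test_real_backend_energy_decreases(self):
        from molprep.chem_model import mol_from_smiles
        from molprep.geometry import DEFAULT_BACKEND

        variants = make_variants(["CCCO"])
        variants[0].mol3d = DEFAULT_BACKEND.embed(variants[0].mol, 1)
        pre = DEFAULT_BACKEND.single_point_energy(variants[0].mol3d)
        out = finalize_variants(variants)
        assert out[0].energy <= pre + 1e-6

    def test_empty_list(self):
        assert finalize_variants([]) == []


class TestStageSeeding:
    def test_distinct_stages_distinct_streams(self):
        seeds = {stage_seed(1, 0, s) for s in ["ionize", "tautomerize", "chirality", "cis_trans"]}
        assert len(seeds) == 4

    def test_reproducible(self):
        a = stage_rng(3, 7, "ionize").integers(0, 1 << 30, 5)
        b = stage_rng(3, 7, "ionize").integers(0, 1 << 30, 5)
        assert np.array_equal(a, b)


class TestFullEnumerationCount:
    def test_two_options_five_categories(self):
        assert full_enumeration_count([2] * 5) == 32

    def test_matches_product_oracle(self):
        for shape in [[1], [2, 3], [2, 2, 2], [4, 1, 3]]:
            assert full_enumeration_count(shape) == math.prod(shape)

    def test_invalid(self):
        with pytest.raises(ValueError):
            full_enumeration_count([2, 0])
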