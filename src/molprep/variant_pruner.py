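"""Bounding the combinatorial explosion of enumerated variants.

After each enumeration stage, at most m*t of the live variants are randomly
sampled (m = max variants per compound, t = thoroughness), one 3D conformer
is embedded per sampled variant, and a single-point force-field energy —
no geometry optimization — ranks them. Only the m best-energy variants
survive. Sets already within the m budget pass through untouched, with no
embedding cost.
"""

from __future__ import annotations

import itertools
import zlib
from collections.abc import Sequence

import numpy as np

from .chem_model import Conformer3D, Variant, canonical_key
from .geometry import DEFAULT_BACKEND, EmbedError, conformer_coordinates


def stage_seed(global_seed: int, molecule_index: int, stage: str) -> int:
    """Deterministic per-(molecule, stage) seed, independent of scheduling."""
    token = f"{global_seed}:{molecule_index}:{stage}".encode()
    return zlib.crc32(token)


def stage_rng(global_seed: int, molecule_index: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, molecule_index, stage))


def prune_variants(
    variants: list[Variant],
    m: int,
    t: int,
    rng: np.random.Generator,
    backend=None,
) -> list[Variant]:
    """Keep at most ``m`` variants, chosen by sampled single-point energies.

    Variants that fail to embed are dropped with a warning; if every sampled
    variant fails, ``EmbedError`` propagates so the caller can flag the
    molecule as failed. Energy ties break on canonical key so the result is
    deterministic.
    """
    if m < 1 or t < 1:
        raise ValueError("m and t must be positive")
    if len(variants) <= m:
        return list(variants)
    backend = backend or DEFAULT_BACKEND

    n_sample = min(len(variants), m * t)
    picked = rng.choice(len(variants), size=n_sample, replace=False)

    scored: list[Variant] = []
    for pos in picked:
        variant = variants[int(pos)]
        embed_seed = int(rng.integers(0, 2**31 - 1))
        try:
            mol3d = backend.embed(variant.mol, embed_seed)
            energy = backend.single_point_energy(mol3d)
        except EmbedError:
            continue
        variant.mol3d = mol3d
        variant.energy = energy
        variant.conformer = Conformer3D(
            coordinates=conformer_coordinates(mol3d), energy=energy, optimized=False
        )
        scored.append(variant)
    if not scored:
        raise EmbedError("no sampled variant could be embedded")

    scored.sort(key=lambda v: (v.energy, canonical_key(v.mol)))
    return scored[:m]


def finalize_variants(
    variants: list[Variant], seed: int = 0, backend=None
) -> list[Variant]:
    """Geometry-optimize every variant that is not already optimized.

    Already-optimized conformers (e.g. from the ring-conformer stage) pass
    through bitwise untouched. Variants without a conformer are embedded
    first. Optimization failures drop the variant rather than aborting.
    """
    backend = backend or DEFAULT_BACKEND
    out: list[Variant] = []
    for i, variant in enumerate(variants):
        if variant.conformer is not None and variant.conformer.optimized:
            out.append(variant)
            continue
        try:
            if variant.mol3d is None or variant.mol3d.GetNumConformers() == 0:
                variant.mol3d = backend.embed(variant.mol, stage_seed(seed, i, "optimize"))
            energy = backend.optimize(variant.mol3d)
        except EmbedError:
            continue
        variant.energy = energy
        variant.conformer = Conformer3D(
            coordinates=conformer_coordinates(variant.mol3d),
            energy=energy,
            optimized=True,
        )
        out.append(variant)
    return out


def full_enumeration_count(options_per_category: Sequence[int]) -> int:
    """Distinct combined forms from independently enumerable state categories.

    Counted by materializing the Cartesian product, not by multiplying, so it
    can serve as an oracle for the pruning stage's bookkeeping.
    """
    if any(n < 1 for n in options_per_category):
        raise ValueError("every category needs at least one option")
    ranges = [range(n) for n in options_per_category]
    return sum(1 for _ in itertools.product(*ranges))
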