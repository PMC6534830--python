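"""End-to-end library preparation: orchestrates all stages over input records.

Stage order per record:

    desalt -> ionize (+ charge prune) -> tautomerize (optional)
           -> chirality -> cis/trans -> 3D (ring-conformer clustering where
           non-aromatic rings exist) -> final geometry optimization

with the random-sampling/energy prune applied after every enumeration stage
so the number of live variants never exceeds ``max_variants_per_compound``.

Per-record failures are collected, never raised: one bad molecule cannot
abort a library run. All randomness derives from (seed, record index, stage
name), so serial and multiprocessing runs produce identical output sets.
"""

from __future__ import annotations

import logging
import multiprocessing
import sys
import warnings
from dataclasses import dataclass, field

from rdkit import Chem

from .chem_model import MoleculeRecord, ProvenanceStep, Variant, canonical_key
from .geometry import DEFAULT_BACKEND, EmbedError
from .protonation import enumerate_ionization_states, prune_by_formal_charge
from .ring_conformers import extract_nonaromatic_rings, select_ring_conformers
from .standardize import desalt
from .stereo_enum import enumerate_chiral, enumerate_cis_trans
from .tautomer_enum import enumerate_tautomers, filter_tautomers
from .variant_pruner import finalize_variants, prune_variants, stage_rng, stage_seed

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """User-facing parameters; defaults follow common library-prep practice."""

    min_ph: float = 6.4
    max_ph: float = 8.4
    pka_precision: float = 1.0
    thoroughness: int = 3
    max_variants_per_compound: int = 5
    skip_making_tautomers: bool = False
    job_manager: str = "serial"  # serial | multiprocessing | mpi
    num_processors: int = 1
    seed: int = 0
    output_sdf: bool = True
    output_pdb: bool = False
    output_html: bool = False

    def __post_init__(self) -> None:
        if self.min_ph > self.max_ph:
            raise ValueError("min_ph must not exceed max_ph")
        if self.max_variants_per_compound < 1:
            raise ValueError("max_variants_per_compound must be >= 1")
        if self.thoroughness < 1:
            raise ValueError("thoroughness must be >= 1")
        if self.pka_precision < 0:
            raise ValueError("pka_precision must be >= 0")
        if self.job_manager not in {"serial", "multiprocessing", "mpi"}:
            raise ValueError(f"unknown job_manager {self.job_manager!r}")


@dataclass
class RecordResult:
    record: MoleculeRecord
    variants: list[Variant] = field(default_factory=list)
    failed: bool = False
    failure_reason: str = ""


@dataclass
class PipelineResult:
    results: list[RecordResult]

    @property
    def successes(self) -> list[RecordResult]:
        return [r for r in self.results if not r.failed]

    @property
    def failures(self) -> list[RecordResult]:
        return [r for r in self.results if r.failed]

    def all_variants(self) -> list[Variant]:
        return [v for r in self.successes for v in r.variants]


def _dedupe(variants: list[Variant]) -> list[Variant]:
    seen: set[str] = set()
    out = []
    for v in variants:
        key = canonical_key(v.mol)
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def prepare_record(
    record: MoleculeRecord, config: PipelineConfig, backend=None
) -> RecordResult:
    """Run the full stage sequence for one input record."""
    backend = backend or DEFAULT_BACKEND
    m = config.max_variants_per_compound
    t = config.thoroughness
    idx = record.source_index

    if record.failed:
        return RecordResult(record, failed=True, failure_reason=record.failure_reason)
    mol = record.to_mol()
    if mol is None:
        return RecordResult(
            record, failed=True, failure_reason=f"unparseable SMILES: {record.smiles!r}"
        )

    try:
        mol, desalt_step = desalt(mol)
        root = Variant(
            parent_id=record.identifier,
            mol=mol,
            provenance=[desalt_step] if desalt_step else [],
        )

        # ionization
        variants = enumerate_ionization_states(
            mol,
            min_ph=config.min_ph,
            max_ph=config.max_ph,
            pka_precision=config.pka_precision,
            parent=root,
        )
        variants = prune_by_formal_charge(variants)
        variants = prune_variants(variants, m, t, stage_rng(config.seed, idx, "ionize"), backend)
        log.debug("%s: %d variants after ionization", record.identifier, len(variants))

        # tautomers
        if not config.skip_making_tautomers:
            pool: list[Variant] = []
            for v in variants:
                candidates = enumerate_tautomers(v.mol)
                pool.extend(filter_tautomers(candidates, v.mol, parent_variant=v))
            variants = _dedupe(pool)
            variants = prune_variants(
                variants, m, t, stage_rng(config.seed, idx, "tautomerize"), backend
            )
            log.debug("%s: %d variants after tautomers", record.identifier, len(variants))

        # chirality
        pool = []
        for v in variants:
            pool.extend(enumerate_chiral(v.mol, parent=v))
        variants = _dedupe(pool)
        variants = prune_variants(variants, m, t, stage_rng(config.seed, idx, "chirality"), backend)
        log.debug("%s: %d variants after chirality", record.identifier, len(variants))

        # cis/trans
        pool = []
        for v in variants:
            pool.extend(enumerate_cis_trans(v.mol, parent=v))
        variants = _dedupe(pool)
        variants = prune_variants(variants, m, t, stage_rng(config.seed, idx, "cis_trans"), backend)
        log.debug("%s: %d variants after cis/trans", record.identifier, len(variants))

        # 3D generation: ring-conformer clustering where applicable
        final: list[Variant] = []
        for v in variants:
            if extract_nonaromatic_rings(v.mol):
                try:
                    mol3d, medoids, conformers = select_ring_conformers(
                        v.mol,
                        n_models=m * t,
                        k_max=m,
                        seed=stage_seed(config.seed, idx, "ring_conformer"),
                        backend=backend,
                    )
                except EmbedError as exc:
                    warnings.warn(f"{record.identifier}: ring embedding failed ({exc})")
                    continue
                for pos in medoids:
                    child = v.child(
                        v.mol, ProvenanceStep("ring_conformer", f"medoid model {pos + 1}")
                    )
                    single = Chem.Mol(mol3d)
                    single.RemoveAllConformers()
                    single.AddConformer(mol3d.GetConformer(pos), assignId=True)
                    child.mol3d = single
                    child.conformer = conformers[pos]
                    child.energy = conformers[pos].energy
                    final.append(child)
            else:
                final.append(v)

        final = finalize_variants(final, seed=stage_seed(config.seed, idx, "optimize"), backend=backend)
        if not final:
            return RecordResult(record, failed=True, failure_reason="no variant could be embedded")

        # ring expansion may have exceeded the budget; keep the best energies
        if len(final) > m:
            final.sort(key=lambda v: (v.energy, canonical_key(v.mol)))
            final = final[:m]
        return RecordResult(record, variants=final)
    except EmbedError as exc:
        return RecordResult(record, failed=True, failure_reason=str(exc))
    except Exception as exc:  # defensive: never abort the batch
        return RecordResult(record, failed=True, failure_reason=f"{type(exc).__name__}: {exc}")


def run_pipeline(
    records: list[MoleculeRecord], config: PipelineConfig, backend=None
) -> PipelineResult:
    """Serial execution over all records."""
    return PipelineResult([prepare_record(r, config, backend) for r in records])


def chunk_inputs(n_inputs: int, n_workers: int) -> list[int]:
    """Split ``n_inputs`` into ``n_workers`` chunk sizes as evenly as possible.

    Sizes sum to ``n_inputs`` and differ by at most one; when the input count
    divides evenly, all chunks are equal.
    """
    if n_inputs < 0:
        raise ValueError("n_inputs must be >= 0")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    base, remainder = divmod(n_inputs, n_workers)
    return [base + 1] * remainder + [base] * (n_workers - remainder)


def _prepare_batch(args: tuple[list[MoleculeRecord], PipelineConfig]) -> list[RecordResult]:
    records, config = args
    return [prepare_record(r, config) for r in records]


def run_parallel(
    records: list[MoleculeRecord], config: PipelineConfig
) -> PipelineResult:
    """Multiprocessing execution; output identical to serial under one seed.

    Work is chunked evenly across workers; per-record seeds depend only on
    the record's source index, so scheduling cannot change the results.
    Falls back to serial (with a warning) where process pools are unusable.
    """
    n_workers = max(1, config.num_processors)
    if config.job_manager == "mpi":
        warnings.warn("mpi job manager not available; falling back to serial execution")
        return run_pipeline(records, config)
    if n_workers == 1 or len(records) <= 1 or sys.platform.startswith("win"):
        if sys.platform.startswith("win") and n_workers > 1:
            warnings.warn("multiprocessing unavailable on this platform; running serially")
        return run_pipeline(records, config)

    sizes = chunk_inputs(len(records), n_workers)
    batches = []
    start = 0
    for size in sizes:
        if size:
            batches.append((records[start : start + size], config))
        start += size

    # fork keeps workers cheap and avoids __main__ re-import; POSIX only,
    # which matches the platforms where this mode is offered at all
    try:
        ctx = multiprocessing.get_context("fork")
    except ValueError:  # pragma: no cover
        ctx = multiprocessing.get_context("spawn")
    with ctx.Pool(processes=n_workers) as pool:
        chunk_results = pool.map(_prepare_batch, batches)

    flat = [res for chunk in chunk_results for res in chunk]
    flat.sort(key=lambda r: r.record.source_index)
    return PipelineResult(flat)
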