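# molprep

Prepare small-molecule libraries for structure-based virtual screening.
`molprep` converts 1D/2D molecular representations (SMILES line files or
flat SDF) into bounded sets of 3D models, enumerating:

- **ionization states** over a user-defined pH window (substructure/pKa
  table; highly charged forms pruned relative to the form closest to
  neutral),
- **tautomers** (rule-based enumeration with filters that reject
  aromaticity-breaking forms, chiral-count changes, terminal-alkene enols,
  geminal vinyl diols, and carbanions),
- **unspecified R/S centers and cis/trans double bonds** (specified stereo
  is never touched),
- **non-aromatic ring conformations** (multiple ETKDG embeddings, UFF
  optimization, per-ring Kabsch-RMSD fingerprints, k-means medoid
  selection).

After each enumeration stage, the live variant set is pruned to at most
`max_variants_per_compound` by random sampling (`m × thoroughness`
candidates) and single-point force-field ranking, so the combinatorial
product of the five state categories never explodes. Output is an SDF with
per-model provenance fields (`Genealogy`, `Parent`, `VariantIndex`),
optionally PDB files and a 2D HTML gallery.

## CLI

```bash
molprep --source library.smi --output_folder out/ \
        --min_ph 6.4 --max_ph 8.4 --pka_precision 1.0 \
        --thoroughness 3 --max_variants_per_compound 5 \
        --job_manager multiprocessing --num_processors 4 --seed 0
```

Add `--skip_making_tautomers` to suppress the tautomer stage,
`--output_pdb` / `--add_html_output` for extra formats, and `--json cfg.json`
to load parameters from a config file. Input format is chosen by extension
(`.sdf` → flat SDF, anything else → SMILES lines). Serial and
multiprocessing modes produce identical outputs under the same seed; `mpi`
is accepted as a flag but falls back to serial execution.

## Python API

```python
from molprep import PipelineConfig, run_pipeline
from molprep.io_formats import read_smiles_file, write_sdf

records = read_smiles_file("library.smi")
result = run_pipeline(records, PipelineConfig(min_ph=7.4, max_ph=7.4, seed=1))
write_sdf(result.all_variants(), "prepared.sdf")
```

## Tests and acceptance report

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite is self-contained: fixture molecules and synthetic libraries
are generated programmatically (`molprep.fixtures`), and geometry-dependent
logic is also exercised against a scriptable stub backend. The acceptance
script recomputes the combinatorial-explosion arithmetic (forms per molecule
under full enumeration, and implied dockings for a 10,000-compound screen)
and writes them as JSON.
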