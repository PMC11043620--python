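# idpflow

Structure–function analysis toolkit for intrinsically disordered protectant
proteins. It chains together, as tested, reusable Python modules, the
quantitative analyses used to connect an IDP's secondary/quaternary structure
to its membrane- and enzyme-protective function:

| Module | What it does |
| --- | --- |
| `idpflow.synthetic_data` | Fixture generators with known ground truth: ideal/unraveling helix trajectories (multi-model PDB), Guinier→power-law scattering curves, DLS correlograms, SLS series, dose-response assay and conductivity tables |
| `idpflow.trajectory_analysis` | Kabsch superposition & RMSD series, geometric H-bond detection (3.5 Å / >120°), residue contact-probability maps, DSSP-style helix/coil timelines, backbone orientational correlation, hydrophobic moments |
| `idpflow.scattering` | Guinier fits with self-consistent window selection (q·R_G ≤ 1.3 SAXS / 1.1 SANS), two-regime Guinier–Porod fits yielding the compaction exponent d, dimensionless Kratky diagnostics, condition trend tables |
| `idpflow.solution_biophysics` | DLS cumulant analysis and Tikhonov-regularized inversion (Stokes–Einstein R_S), SLS apparent mass with infinite-dilution extrapolation (M_rel), crowder volume fractions, CD helix fractions |
| `idpflow.protection_assays` | Lipids-per-vesicle and surface-occupancy normalization, CF-leakage percentages, 4-parameter-logistic dose-response fits (stabilization capacity), LT50 from electrolyte leakage, LDH activity retention |
| `idpflow.pipeline_cli` | Configuration, orchestration and the `idpflow` command line |

## CLI

```bash
idpflow --help
idpflow simulate --kind saxs --seed 42 --out saxs.dat   # synthetic fixture
idpflow guinier saxs.dat                                # R_G + window report
idpflow gpfit saxs.dat                                  # R_G and exponent d
idpflow dls correlogram.csv --method regularized        # R_S distribution
idpflow occupancy --c-prot 1 --rs-prot 2.5 --mw-prot 15000 \
        --target protein --c-target 0.15 --mw-target 140000
idpflow run --seed 7 --outdir out/                      # full synthetic study
```

`idpflow run` executes every stage end-to-end on seeded synthetic data and
writes TSV artifacts plus a schema-versioned `report.json`; reruns with the
same seed are byte-identical. Configuration may also come from a JSON file
(`--config`); unknown keys are rejected before any computation.

## Notes

- Trajectories are plain multi-model PDB (chains A/B, optional HOH solvent);
  scattering curves are 3-column ASCII with `#` headers; assay inputs are CSV.
- All generators are pure functions of their parameters and an explicit seed.
- `tests/test_acceptance.py` contains one test per acceptance criterion; the
  COR15A counterion check requires the AT2G42540.2 sequence as
  `src/idpflow/data/AT2G42540.2.fasta` and fails with an explanatory message
  when that file is absent.
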