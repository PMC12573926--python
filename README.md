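# ssxdamage

Radiation-damage analysis toolkit for serial crystallography on
**unpatterned sheet-on-sheet fixed targets**: serpentine raster-scan
exposure modelling, Monte-Carlo merging of snapshot reflection lists,
bootstrap uncertainty on refined heme-site geometry, distribution-level
beamtime comparison, Wilson-B global-damage diagnostics, unit-cell
population tracking, and dose bookkeeping — exercised end to end on a
synthetic snapshot-diffraction generator with known ground truth.

## Layout

| module                | what it does |
|-----------------------|--------------|
| `ssxdamage.scan`      | serpentine exposure schedules, time/distance structure, damage-spread and multiple-hit models, conduction kernel |
| `ssxdamage.synth`     | toy heme-site structures with exact requested geometry, partial snapshot reflection lists with planted Wilson B, two unit-cell populations, saturation clipping, coordinate ensembles |
| `ssxdamage.merging`   | Monte-Carlo merging, resolution shells, S/N resolution cut-off, clipping reports |
| `ssxdamage.refine`    | toy structure-factor calculator and Levenberg–Marquardt intensity refinement; coordinate scrambling; two-conformer water occupancy refinement |
| `ssxdamage.geometry`  | PDB reading/writing, heme role assignment, least-squares plane fits, Fe–Wat / Fe–His / FeOOP / O–O / angle / H-bond measurements |
| `ssxdamage.stats`     | image bootstrap (drawing with replacement), Gaussian-mixture combination, Welch's t-test, weighted step-size trend tests |
| `ssxdamage.wilson`    | observed and calculated-intensity Wilson plots, excess-B recovery, falloff ratios, k-means unit-cell clustering |
| `ssxdamage.dose`      | photons per pulse from ring-current scaling, dose rates, a simple absorbed-dose estimate |
| `ssxdamage.io` / `.cli` | reflection TSV dialect, config handling, the `ssxdamage` command line |

## Command line

All stages compose through a TSV reflection dialect (one observation per
row: `image_id a b c alpha beta gamma h k l I sigma`):

```sh
ssxdamage simulate --config configs/example_study.yaml --seed 1 --out refl.tsv
ssxdamage merge refl.tsv --out merged.tsv
ssxdamage wilson refl.tsv --out wilson.csv
ssxdamage cells refl.tsv --out cells.csv
ssxdamage scan --step-fast 25 --step-slow 25 --rate 231.25 --out scan.csv
ssxdamage geometry structure.pdb --out geometry.json
ssxdamage bootstrap structure.pdb refl.tsv --n-replicas 100 --out boot.json
ssxdamage dose --dose-mgy 0.88
ssxdamage run-all --config configs/example_study.yaml --out results/
```

`run-all` simulates per-step-size datasets, merges them, bootstraps the
scramble→refine→measure pipeline, and assembles trend tests, Gaussian-sum
beamtime comparisons (Welch), Wilson fits and cell-population fractions
into one seed-stamped JSON bundle.  Reruns with the same config are
byte-identical.

## Conventions worth knowing

- Wilson slope convention: shell-mean intensity `<I> ∝ exp(−B/(2d²))`,
  so the fitted line in `ln<I>` vs `1/d²` has slope `−B/2`.  Observed fits
  exclude `1/d² < 0.1 Å⁻²` by default.  Planted-B recovery uses the
  observed-minus-calculated *excess* B over a matched fit range, which
  cancels the structure's own interference term.
- FeOOP is signed positive toward the distal (water) side of the
  four-pyrrole-nitrogen least-squares plane (a 24-atom-core plane is an
  option).
- The refinement target is intensity-based least squares with no
  geometric restraints; in P1 the intensities are blind to a global origin
  translation, so positional recovery is defined modulo that translation.
- The conduction kernel in `scan.thermal_increment` is a documented
  stand-in (instantaneous point/sheet source in an infinite medium), not a
  full heat/gas-diffusion treatment.
- Diffraction-weighted doses are inputs (see `configs/beamlines.yaml`),
  never recomputed.
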