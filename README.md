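# afmi

Analysis toolkit for autofluorescence multispectral imaging (AFMI) of ocular
surface tissue: discriminating normal conjunctiva, pterygium (PTG), and
ocular surface squamous neoplasia (OSSN) from 59-channel fluorescence image
stacks.

The package implements the full analysis chain:

1. **Channel model** (`afmi.channels`) — the 59-channel excitation/emission
   scheme with fluorophore attributions (channel 3 elastin, 12 lipopigment,
   30 flavins, 52 PPIX), loaded from a bundled CSV or user files.
2. **Synthetic phantoms** (`afmi.phantom`) — multipatient cohorts of
   59-channel tissue stacks with known class geometry, per-patient affine
   spectral variability, smooth within-class texture, and camera
   degradations (background fluorescence, illumination vignetting, dead and
   saturated pixels, Poisson noise), with full ground truth retained.
3. **Preprocessing** (`afmi.preprocess`) — bad-pixel repair, background
   subtraction, polynomial flat-field correction (alternating least squares
   against the tissue label mask), and translation-only tile stitching by
   phase correlation.
4. **Spectral signatures** (`afmi.signatures`) — 16×16-pixel sector tiling,
   per-sector 59-dimensional mean spectra, and the per-patient relative
   normalization `rss = (ss − med) / std` against each patient's own
   normal-tissue reference.
5. **Classification** (`afmi.classify`) — PCA compression to the top five
   scores, SVM classifiers, rank-based ROC/AUC, and K-fold /
   leave-one-patient-out cross-validation under three frameworks: fused
   (cross-patient training on normalized signatures), inter-patient (raw
   signatures), and intra-patient.
6. **Boundary maps** (`afmi.boundary`) — intra-patient training and
   red (OSSN) / orange (PTG) / green (normal) false-color sector overlays,
   optional majority-filter smoothing, and PCA false-color rendering.
7. **Channel statistics** (`afmi.channel_stats`) — per-channel two-tailed
   Mann–Whitney U comparisons between tissue classes with star annotation.
8. **Pipeline** (`afmi.pipeline`, `afmi.cli`) — end-to-end orchestration
   with deterministic seeding and JSON/CSV artifacts.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (channel-scheme
fidelity, PCA variance capture, normalization exactness, oracle
equivalences, fused-vs-inter-patient direction, boundary recovery,
statistical calibration, determinism). A 20-patient evaluation cohort is
generated once per session; the full suite takes a few minutes on one CPU.

## CLI

```bash
afmi simulate  --out data/ --seed 1 --patients 6
afmi preprocess --in data/ --out clean/
afmi signatures --in clean/ --out signatures.csv
afmi classify  --signatures signatures.csv --framework fused --task ptg-vs-ossn --cv kfold:10
afmi map       --stack clean/P01_stack.tif --mask clean/P01_mask.tif --out maps/
afmi stats     --signatures signatures.csv --channels 3,12,30,52
afmi run       --config run.yaml
```

`afmi run` executes a multi-stage experiment from a YAML config, e.g.

```yaml
stages: [simulate, preprocess, signatures, classify, stats]
seed: 1
output_dir: out/
simulate: {n_patients: 10, image_shape: [256, 256]}
classify: {task: ptg-vs-ossn, framework: fused, cv: kfold, k: 10}
stats: {channels: [3, 12, 30, 52], mode: patients}
```

Identical config + seed reproduces every artifact bit-for-bit (summary JSON
excludes timestamps).

## Notes

- Real patient imagery is not bundled; all evaluation runs on synthetic
  phantoms whose generator encodes the qualitative class contrasts of the
  fluorophore channels (elastin reduced in PTG and further in OSSN;
  lipopigment elevated in OSSN; flavins and PPIX reduced in OSSN).
- Sector signatures are means over all 256 pixels of a sector; sectors with
  partial tissue coverage are flagged via `tissue_fraction` and excluded
  from normal references, training rows, and group statistics.
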