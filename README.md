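# nosomap

Train brain-tumor classifiers on single-voxel (SV) MR spectra and apply
them voxel-by-voxel to multivoxel (MV) grids, producing color-coded
nosological maps. Because the clinical databases this style of analysis
was developed on are not publicly available, the package ships a
first-class synthetic-data module that generates labeled SV training
sets and MV test phantoms with the relevant spectral structure and
artifact types (flipped spectra, residual water, low SNR, frequency
misalignment, ghosting).

## Pipeline

1. **`nosomap.synth`** — forward model: class-specific Lorentzian
   resonance profiles (mm / gb / me / lgg / no) plus a macromolecule
   baseline, rendered as complex FIDs; SV datasets and spatial MV
   phantoms with ground-truth masks (normal / solid / abnormal /
   ventricle) and partial-volume "voxel bleeding" at region boundaries.
2. **`nosomap.processing`** — canonicalization: HLSVD water removal
   (Hankel-SVD estimation of damped sinusoids in [4.31, 5.11] ppm), FFT,
   resampling to the fixed 512-point [−2.7, 7.1] ppm grid, flip
   correction, reference-peak alignment (2.01 → 3.21 → 3.03 ppm
   priority), [4.2, 5.1] ppm zeroing, unit-length (UL2) normalization,
   and [0, 4.2] ppm re-extraction (indices 152..370, renormalized).
3. **`nosomap.qc`** — voxel quality control: SNR threshold (< 10
   discarded) and convex-NMF screening — spectra whose largest mixing
   contribution comes from an artifact-flagged source are discarded.
4. **`nosomap.features`** — SFFS (floating forward selection with an
   LDA wrapper, stratified CV balanced accuracy) plus Chi / K-best /
   Lasso / Boruta baselines; Pearson-correlation redundancy dropping
   (the higher-ppm member of pairs with r > 0.8 is removed).
5. **`nosomap.classify`** — in-package LDA (reference), RF/SVM
   baselines, BER / one-vs-rest AUC, 1000-replicate stratified bootstrap
   evaluation, and best-model selection by the test/train AUC-ratio
   criterion.
6. **`nosomap.nosology`** — nosological maps (blue = normal, red =
   aggressive, green = lgg, yellow = mm; excluded voxels black at 0.5
   alpha, intensity = winning posterior), Solid Tumor Index (STI), Dice
   scores, and per-grid BER/AUC on solid + normal voxels.
7. **`nosomap.io` / `nosomap.cli`** — XML spectra/mask dialect,
   delimited tables, PNG rendering, and the umbrella CLI.

## CLI

All stages are exposed as subcommands of the `nosomap` entry point
(equivalently `python -m nosomap.cli`):

```sh
nosomap simulate --kind sv --out run/sv --seed 1 --n-per-class "no=22,mm=62,agg=123,lgg=35"
nosomap process --in run/sv/spectra.xml --out run/sv
nosomap simulate --kind phantom --out run/ph --seed 2 --case-class gb --dims 18,14,1
nosomap process --in run/ph/spectra.xml --out run/ph
nosomap qc --features run/ph/features.xml --canonical run/ph/canonical.xml \
    --mask run/ph/mask.xml --out run/ph
nosomap select-features --features run/sv/features.xml --method sffs --k 8 \
    --out run/features.tsv
nosomap train --features run/sv/features.xml --feature-set run/features.tsv \
    --out run/model.json
nosomap classify-grid --model run/model.json --features run/ph/features.xml \
    --qc run/ph/qc.tsv --mask run/ph/mask.xml --out run/map.tsv
nosomap score --map run/map.tsv --mask run/ph/mask.xml --out run/scores.tsv
nosomap render --map run/map.tsv --mask run/ph/mask.xml --out run/map.png
```

`nosomap end-to-end --out run/e2e --seed 7` runs the whole chain
(simulate → process → QC → select → train → classify → score → render)
deterministically; every subcommand writes a `manifest.json` with the
seed and config hash so runs can be replayed exactly.

## Format notes

Spectra XML: `<spectra representation="fid|canonical|feature">` with one
`<record id=.. label=..>` per spectrum; FIDs carry acquisition metadata
(`dwell_time`, `transmitter_frequency`, `reference_ppm`) and real/imag
sample vectors; canonical records hold exactly 512 values on
`ppm(i) = 7.1 − i · 9.8/511`. Masks: `<mask nx= ny= nz= case_class=>`
with per-slice rows of `normal|solid|abnormal|ventricle` tokens.
Proprietary scanner formats (DICOM MRS, SDAT/SPAR, RDA, GE Probe) are
out of scope; `read_spectra` is the seam for future adapters.
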