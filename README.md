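# stprf

Spatiotemporal population-receptive-field (pRF) encoding models and a
simultaneous-suppression analysis pipeline for block-design visual fMRI,
exercisable end to end on synthetic voxel populations (no data downloads).

## What it does

* **Stimulus generation** (`stprf.stimulus`): the SEQ-SIM protocol — 2×2
  square groups in two diagonal quadrants shown sequentially or
  simultaneously, at two presentation timings (0.2 s / 1 s) and two sizes
  (2° / 4°), in 8-s blocks with 12-s blanks — plus a 12-step sweeping-bar
  retinotopy protocol. Stimuli are exact millisecond event lists; transient
  counting and rasterization utilities included.
* **Encoding models** (`stprf.prf_models`): linear spatial summation (LSS),
  compressive spatial summation (CSS), compressive spatiotemporal summation
  (CST, sustained + on/off-transient channels with gamma impulse responses,
  rectification and a shared power law), difference of Gaussians (DoG), and
  delayed divisive normalization (DN-ST). The spatial stage is evaluated in
  closed form (Gaussian × rectangle integrals).
* **Hemodynamics** (`stprf.hemodynamics`): canonical double-gamma HRF,
  causal convolution and TR box-car downsampling.
* **Fitting** (`stprf.fitting`): OLS with split-half cross-validation
  (betas fixed across halves), adjusted cv-R², grid fit of the
  spatiotemporal exponent, two-stage (grid + local search) compressive
  retinotopy fit, split-half reliability (noise ceiling), and the voxel
  inclusion filters.
* **Suppression analysis** (`stprf.suppression`): 23-TR block-window
  segmentation, 9-TR peak-window amplitudes with the 10 %-cumulative-sum
  start rule, a linear mixed model relating simultaneous to sequential
  amplitudes per condition with participant random effects (the fixed
  slopes quantify suppression; 1 = none), mixed-model variant comparison,
  and bootstrap parameter summaries.
* **Synthetic data** (`stprf.synthetic`): ground-truth voxel populations
  with per-area distributions of pRF position/size/exponent/channel
  weights, forward BOLD simulation through any encoding model, and noise
  calibrated in closed form to a target split-half reliability.
* **Orchestration** (`stprf.pipeline`, `stprf.cli`): end-to-end runs with
  manifests, TSV/JSON interchange formats, optional NIfTI ingestion.

## CLI

```bash
stprf simulate-stimulus --seed 1 --out out/stim      # schedules as TSV
stprf make-synthetic --seed 1 --out out/synth        # synthetic voxel TSVs
stprf predict --model cst --params params.tsv --out preds.tsv
stprf fit --model css --voxels out/synth/voxels.tsv \
      --params out/synth/ground_truth.tsv --out fits.tsv
stprf suppress --amplitudes table.tsv --out out/lmm
stprf run-all --seed 1 --out out/full                # whole pipeline
stprf report --results out/full
```

All verbs accept `--seed`; `run-all`/`make-synthetic` accept a JSON/YAML
`--config` (see `stprf.pipeline.PipelineConfig`).

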