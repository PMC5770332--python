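# fearmvpa

Synthetic fear-conditioning fMRI/SCR data and an MVPA threat-decoding
pipeline: single-trial BOLD amplitude estimation, imbalance-aware
permutation-corrected SVM decoding, simple/complex cross-classification,
searchlight mapping with sign-flip group inference, model-based
skin-conductance arousal estimation, and factorial mixed-effects
statistics.

## What it does

The package simulates and analyses a differential fear-conditioning
experiment with auditory stimuli.  Eight sounds (2 contexts x 2
complexities x 2 stimuli) are presented in 8 blocks of 2 miniblocks of 12
trials; in the reinforced context, half the CS+ presentations co-terminate
with an aversive stimulation, while neutral sounds (NS) are never
reinforced.  The analysis chain asks whether multivoxel response patterns
separate CS+ from CS- over and above the physical stimulus separation
measured on NS pairs, and whether that threat code transfers between
simple and complex sounds.

Modules (`src/fearmvpa/`):

- `synth` — experiment designs (`design`), 4-D BOLD runs with planted
  multivoxel patterns (`bold`), and skin-conductance traces (`scr`).
  Ground truth is stored with every simulation for recovery testing.
- `hemo` — canonical double-gamma HRF and event-regressor construction on
  a 0.1 s microtime grid.
- `glm` — least-squares-all single-trial GLM: one 3.5 s boxcar regressor
  per trial, a pooled US regressor, a 128 s DCT high-pass basis plus
  intercept, and optional nuisance columns; returns a trials x voxels beta
  series with reinforced trials flagged unusable.
- `arousal` — per-trial anticipatory arousal from SCR traces: joint
  non-negative fit of a canonical gamma-difference response kernel with
  onset latency optimized on a 0.25 s grid inside 0-3.5 s after sound
  onset, followed by within-subject z-normalization and condition means.
- `decoding` — per-voxel z-scoring, 3-fold cross-validation (every third
  trial is test data), linear-kernel SVM, chance estimation from label
  permutations under the 12:24 imbalance, 50% subsampling of one neutral
  class to match that imbalance, and cross-classification between
  complexities.
- `searchlight` — 10 mm spherical searchlight producing corrected-accuracy
  maps and a CS-NS contrast map; group inference by one-sample t with
  sign-flip max-statistic FWE control.
- `group` — balanced 2^k within-subject mixed models (random subject
  intercept, containment denominator df = N - subjects - within
  parameters), Wilcoxon post-hocs, and the volume-corrected
  region-size/learning correlation.

## CLI

```sh
fearmvpa simulate design --seed 1 --out out/            # events.tsv
fearmvpa simulate bold   --seed 1 --out out/            # bold.nii + roi_labels.nii
fearmvpa simulate scr    --seed 1 --out out/            # scr.tsv
fearmvpa glm    --bold out/bold.nii --events out/events.tsv \
                --mask out/roi_labels.nii --tr 2.5 --out glm/
fearmvpa scr    --trace out/scr.tsv --events out/events.tsv --out scr/
fearmvpa decode --betas glm/betas.nii --events out/events.tsv \
                --roi-labels out/roi_labels.nii --n-perm 1000 --n-rep 100 \
                --seed 1 --out decoding.tsv
fearmvpa searchlight --betas glm/betas.nii --events out/events.tsv \
                --mask mask.nii --radius 10 --seed 1 --out sl/
fearmvpa group  --table table.tsv --model context*complexity*hemisphere \
                --out ftable.tsv
```

`simulate` subcommands accept `--config config.yaml` with `design`, `roi`,
`effects`, `bold`, and `scr` sections mirroring the keyword arguments of
the corresponding Python functions.

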