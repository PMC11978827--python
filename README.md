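# neurofusion

Cross-modal alignment of fMRI voxel signals and natural images, at desk
scale and fully self-contained. The pipeline:

1. **Voxel embedding** — each voxel's 3D coordinate is lifted through an
   affine map; the per-timestep amplitude sequence (voxels serialized in a
   fixed ascending (z, y, x) order) is tokenized by a strided 1D convolution
   (kernel 32, stride 16 by default) and fused with the mean coordinate
   embedding over each token's receptive field.
2. **Sliced-window transformer** — the token sequence is cut into
   overlapping windows (width w=64, stride s=32, h=2 stacked layers by
   default); each window passes through a pre-norm transformer block with
   padding masked out of attention, overlaps are reassembled by position-wise
   averaging, and the final sequence is pooled into one global signal feature
   plus one feature per ROI.
3. **Vision encoder** — a small self-contained conv backbone (`tiny_conv`,
   four stages to a 7×7 grid) with a global projection head and one local
   head per brain ROI.
4. **Objectives** — a symmetric temperature-scaled contrastive loss over
   global features plus an ROI-guided loss aligning each image-local feature
   with its matching ROI feature against the other ROIs; a fusion transformer
   block combines both modalities and feeds a linear voxel-prediction head.
5. **Evaluation** — cross-modal retrieval top-k, voxel-wise Pearson
   correlation of predicted responses, and standalone IoU / mean-IoU /
   average-precision metric primitives.

Because no brain-imaging corpus ships with the package, a **synthetic data
generator** produces paired (image, voxel-response) samples with the structure
of a naturalistic-scenes fMRI corpus — spatially contiguous ROIs on an integer lattice and a tunable
latent coupling between image content and ROI responses — so every component
is testable offline, including whether training actually recovers a planted
cross-modal alignment.

There is no deep-learning framework dependency: training runs on a small
in-repo reverse-mode autodiff engine over numpy (`neurofusion.autodiff`,
`neurofusion.nn`), gradient-checked against finite differences.

## CLI

```bash
neurofusion simulate --config cfg.yaml --out data/     # synthetic dataset
neurofusion train    --config cfg.yaml --data data/ --out run/
neurofusion evaluate --run run/ --report report.json
neurofusion embed    --config cfg.yaml --data data/ --out feats.h5
```

`cfg.yaml` is optional; an empty file gives the defaults (w=64, s=32, h=2,
six ROIs, conv kernel 32 / stride 16, lr 1e-4, 224×224 images). Example:

```yaml
synthetic: {n_samples: 320, n_vox: 60, n_roi: 6, img_size: 56, seed: 1}
model: {d: 32}
timeformer: {w: 64, s: 32, h: 2}
loss: {sigma: 0.07, lambda_con: 1.0, lambda_bfg: 1.0}
train: {lr: 0.001, epochs: 30, batch_size: 32, seed: 1}
```

Unknown keys are rejected with a suggestion. A simulated dataset directory
holds a 4D NIfTI signal volume + integer NIfTI ROI mask, PNG images, and an
HDF5 sidecar with the ground-truth latents; `neurofusion train` writes the
effective config, a JSON evaluation report, a plain-text loss log, and the
visual backbone as a checksummed weight archive.

## Layout

```
src/neurofusion/
  autodiff.py        # numpy reverse-mode autodiff engine
  nn.py              # Linear / LayerNorm / Conv2d / attention / Adam
  synthetic_data.py  # paired-sample generator with known latent coupling
  voxel_embedding.py # voxel grid, coordinate embedding, conv tokenizer
  timeformer.py      # sliced-window transformer encoder
  vision_encoder.py  # tiny_conv backbone + per-ROI heads + weight archive
  fusion_losses.py   # contrastive / ROI-guided losses, fusion block
  model.py           # joint cross-modal model
  training_eval.py   # training loop, retrieval, PCC, IoU/mIoU/AP
  io_utils.py        # NIfTI / PNG / HDF5 readers and writers
  config.py          # strict YAML run configuration
  cli.py             # click CLI
```
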