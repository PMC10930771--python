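# magnet

End-to-end, weakly supervised classification of gigapixel multi-resolution
image pyramids by recursive differentiable magnification.

A *magnifying network* starts from a 56 × 56 whole-slide view and stacks
*magnifying layers*: each layer localises regions of interest with
patch-specific convolutional "Branches" and a spatial sparsemax, infers an
affine crop (isotropic scale + translation, constrained by
`s = max(s, 0.05)`, `t = tanh(t)`), and materialises each crop with a
linearized multi-sampling grid sampler from a higher-fidelity source view
that is freshly read from the pyramid at a dynamically selected
magnification level. Final-layer patches (224 × 224) feed a CNN backbone,
a GRU over the patch sequence, and a fully connected head that outputs a
slide-level probability. Training uses only slide-level labels with the
summed objective: paradoxical loss between the layer-1 and layer-3
auxiliary classifiers, their cross-entropy terms, and the head
cross-entropy.

Everything runs on plain numpy (a small reverse-mode autodiff engine is
included), so no GPU or deep-learning framework is required.  Because the
reference configuration relies on ImageNet-pretrained backbones, the
trainer offers an optional two-phase desk schedule
(`head_finetune_epochs`): after the main loop the classification backbone
is initialised from the trained deep auxiliary classifier and only the
GRU + FC head is fine-tuned with the attention frozen.

## CLI

```bash
# generate a labelled synthetic dataset of pyramids with planted lesions
magnet synth --n 200 --out data/ --seed 1 --lesion-scale micro

# train (defaults follow the reference recipe; YAML overrides optional)
magnet train --config cfg.yaml --data data/ --out run/

# evaluate a checkpoint (AUROC via the rank statistic, accuracy at 0.5)
magnet eval --weights run/checkpoint.npz --data data/ --by-stratum

# render the forward-pass patch trace (hierarchical names I1, I11, I131...)
magnet trace --weights run/checkpoint.npz --slide data/slide_0000 --out trace.png
```

Pyramids are directories with `level_<k>.png` rasters (level k halves the
resolution of level k−1) plus `meta.json`; multi-page pyramidal TIFF is
supported read-only via `magnet.pyramid.load_tiff_pyramid`.

## Package layout

| module | contents |
| --- | --- |
| `magnet.pyramid` | pyramid stack, level selection, region reads, frame composition, IO |
| `magnet.synth` | synthetic labelled pyramids with planted multi-scale lesions |
| `magnet.preprocess` | grey filter (spread < 15 → black), resize/pad, dihedral augmentation |
| `magnet.attention` | Branch localiser, sparsemax, affine inference/constraints, grid + samplers |
| `magnet.model` | magnifying layers, classification head, auxiliary classifiers, patch traces |
| `magnet.losses` | paradoxical loss, BCE, total loss |
| `magnet.train` | Adam + cosine schedule training loop, evaluation, manifests |
| `magnet.nn`, `magnet._tensor`, `magnet._sampling` | numpy autodiff engine and samplers |
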