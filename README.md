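# mtef — multistage wavelet-enhanced multimodal 3D registration

`mtef` is a research tool for **unsupervised deformable registration of
multimodal 3D medical volumes** — the CT/MR alignment problem of
image-guided radiotherapy planning, where pelvic organs (bladder, CTV,
femur, intestine) undergo large, locally discontinuous deformation and
the two modalities assign completely different intensities to the same
tissue.

Given a fixed volume *I* and moving volume *M*, the tool estimates a
dense displacement field ϕ so that the warped image
`(M∘ϕ)(x) = M(x + ϕ(x))` aligns with *I*. Four ideas work together:

1. **Wavelet multi-resolution inputs.** A three-level 3D DWT (db5)
   splits each volume into an approximation `aaa` and seven detail
   subbands per level; the detail bands are fused into an enhancement
   image `E = Σ|∇b|` that highlights local structure independently of
   the modality's intensity mapping.
2. **Shared pyramid registration network (SPR-Net).** Two independent
   windowed-attention encoders (one per modality) and a shared
   convolutional decoder that predicts the field coarse→fine, warping
   moving features with the upsampled running field at every level.
   Refinement heads are zero-initialised, so an untrained network is the
   identity transform.
3. **Four-stage cascade.** Stage inputs go global → local → global:
   `aaa` (1/8 grid) → `E` (1/4) → `E` (1/2) → original volumes (full),
   with fields accumulated across stages by composition
   `ϕ_ref ∘ ϕ_acc + ϕ_acc`.
4. **Self-supervised similarity evaluator.** A 3D residual CNN trained
   to regress the spatial error `mean |M2 − M1|` between two transforms
   of one volume while seeing only a corrupted copy (dual-structure
   ring-morphology + noise) — forcing it to measure misalignment through
   appearance change. It plugs into training as a differentiable loss;
   a regularised local squared-correlation loss is the built-in
   alternative.

Quality is reported as Dice similarity coefficient (DSC), average
symmetric surface distance (ASSD) and the percentage of folded voxels
(Jacobian determinant ≤ 0).

Everything — including the windowed-attention networks and their Adam
training — runs on plain numpy via a small reverse-mode autodiff engine
in `mtef.nn`, sized for desk-scale volumes. A synthetic phantom
generator (`mtef.phantom`) produces co-registered pseudo-CT/pseudo-MR
pairs with rank-different tissue contrasts, organ labels and known
ground-truth deformation, and is used by all validation studies.

## Worked example

```python
import numpy as np
from mtef.phantom import PhantomSpec, generate_pair
from mtef.cascade import CascadeConfig, make_nets, register
from mtef.sprnet import NetConfig
from mtef.trainloop import TrainConfig, fit
from mtef import metrics

# phantom pairs: pseudo-CT fixed, deformed pseudo-MR moving
cases = [generate_pair(PhantomSpec(seed=s)) for s in range(13)]
train = [(c[0], c[1]) for c in cases[:12]]

cfg = CascadeConfig(net=NetConfig(embed_dim=8, depths=(1, 1, 1),
                                  heads=(2, 4, 4), window=4,
                                  decoder_hidden=16, decoder_depth=2))
nets = make_nets(cfg)
tcfg = TrainConfig(iterations=300, base_lr=1e-3, warmup=50, batch_size=2,
                   similarity="ncc", ncc_window=5, seed=0)
nets, history = fit(train, nets, tcfg, cfg)

fixed, moving, flab, mlab, _ = cases[12]         # held-out pair
result = register(fixed, moving, cfg, nets)
rep = metrics.report(flab, mlab, result.field)
print(f"pre-DSC  {np.mean(list(rep.pre_dsc_per_label.values())):.3f}")
print(f"post-DSC {np.mean(list(rep.dsc_per_label.values())):.3f}")
print(f"JD<=0    {rep.jd_nonpositive_percent:.2f}%")
```

Output:

```
pre-DSC  0.702
post-DSC 0.804
JD<=0    0.00%
```

The mean label overlap of the held-out pair improves from the
unregistered 0.70 to 0.80 after only 300 desk-scale iterations, and the
predicted field is entirely fold-free — the coarse-to-fine cascade moves
organs without tearing the grid. Training
at clinical scale (full 12-layer encoders, 15 000 iterations) uses the
same code paths with `NetConfig()` defaults.

The same pipeline is scriptable from the shell:

```bash
mtef phantom --out suite --n 10 --seed 1
mtef train --data suite --out run --iterations 300
mtef register --fixed suite/case008_fixed.nii.gz \
              --moving suite/case008_moving.nii.gz \
              --nets run/nets --out reg
mtef evaluate --fixed-labels suite/case008_fixed_labels.nii.gz \
              --moving-labels suite/case008_moving_labels.nii.gz \
              --field reg/field.nii.gz --out metrics.json
```

## Layout

```
src/mtef/
  volio.py       NIfTI I/O, resampling, normalisation, cropping
  wavelet3d.py   3-level 3D DWT, subband naming, enhancement image E
  defield.py     displacement fields: warp, compose, resize, Jacobian
  sprnet.py      dual-encoder + shared pyramid decoder network
  cascade.py     four-stage coarse-to-fine orchestration
  bimorph.py     dual-structure (ring) grey-scale morphology, top-hats
  simeval.py     transform sampling, evaluator training, similarities
  trainloop.py   loss assembly, LR schedule, Adam fitting, logging
  metrics.py     DSC, ASSD, JD≤0 reporting
  phantom.py     synthetic multimodal phantom generator
  experiments.py desk-scale validation studies
  nn/            numpy autodiff engine, layers, Adam
  cli.py         `mtef` command group
docs/methods.md  model assumptions, parameters, numerical choices
```
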