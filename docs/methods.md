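# Methods

## Problem setting

Given a fixed volume *I* (CT-like) and a moving volume *M* (MR-like) on a
common grid, deformable registration seeks a dense displacement field ϕ
such that the warped image M∘ϕ, defined by `(M∘ϕ)(x) = M(x + ϕ(x))`, is
spatially aligned with *I*. In pelvic imaging the deformation is large and
locally discontinuous (bladder filling, rectal motion), and the two
modalities map the same tissue to very different intensities, so neither a
single-resolution network nor a mono-modal similarity suffices. The
package addresses both difficulties with (i) wavelet-derived
multi-resolution inputs, (ii) a four-stage coarse-to-fine cascade of
pyramid registration networks, and (iii) a learned similarity evaluator
trained with dual-structure morphology corruption.

## Wavelet inputs

Each volume is decomposed with a three-level 3D discrete wavelet transform
(default basis `db5`). Every level yields eight subbands coded by the
filter per axis (`a` low-pass, `d` high-pass): `aaa` is the approximation;
the seven `d`-containing bands are detail. Periodization boundary handling
is used so each level halves every axis exactly — a 384×256×32 volume has
a level-3 `aaa` of 48×32×4 — while retaining perfect reconstruction and
exact energy preservation for orthogonal bases.

The enhancement image is

    E = Σ_b |∇b|,   b ∈ {aad, ada, add, daa, dad, dda, ddd} (level 1),

where ∇ is the per-band central-difference gradient and |·| the voxelwise
magnitude. Summing magnitudes (rather than vector fields) makes E a
non-negative edge/texture map; it is insensitive to the absolute intensity
mapping of the modality and to global intensity offsets, which is exactly
why it is a useful *multimodal* registration input. E is min–max
normalised to [0, 1] before entering a network so all cascade levels share
an intensity scale.

## Shared pyramid registration network (SPR-Net)

Each cascade stage runs an SPR-Net: two *independent* hierarchical
windowed-attention encoders (one per modality; same architecture,
separate parameters) and a *shared* convolutional pyramid decoder.

Encoder. The input is cut into non-overlapping K×K×K patches
(S = HWL/K³ tokens) and linearly embedded to dimension D; no positional
embedding is added — the training loss is itself spatial, so absolute
position information is redundant. Stages alternate plain and
half-window-shifted window attention (cyclic shift + additive mask),
pre-norm residual blocks with MLPs, and patch merging between stages
(×½ resolution, ×2 channels: D → 2D → 4D → 8D). Window extents are
clamped to the feature-map size, and feature maps are zero-padded to
window multiples, so small desk-scale grids are handled without special
cases. A CNN encoder of the same pyramid contract is available as an
ablation (`encoder="cnn"`).

Decoder. From the deepest level upwards: the running field is upsampled
(×2 grid, ×2 magnitude, since displacements are stored in voxel units of
their own grid), the moving features are warped with it, concatenated with
the fixed features, the upsampled field and (when skip connections are
enabled) the upsampled decoder state; a 3×3×3 convolution produces the
decoder state and a second, *zero-initialised* 3×3×3 convolution emits a
refinement δ, accumulated by composition `δ∘ϕ + ϕ`. Zero-initialised
refinement heads make the untrained network exactly the identity
transform, which keeps the downstream cascade stable at the start of
training.

## Four-stage cascade

Stage inputs alternate global and local descriptions: level 3 registers
the `aaa` approximations (global, 1/8 grid), levels 2 and 1 the
enhancement images E (local detail; the same level-1 E resampled to the
1/4 and 1/2 grids), and level 0 the original normalised volumes (full
grid). At each stage the accumulated field is upsampled to the stage grid,
the stage's moving representation is warped with it, the stage SPR-Net
predicts a refinement, and composition accumulates. Two fidelity choices:

* Stage representations are computed once from the original moving volume
  and then warped, rather than re-deriving wavelet images from repeatedly
  warped volumes. This avoids compounding interpolation error and keeps
  the full forward pass differentiable through the field-composition
  chain (stage inputs are treated as constants for the encoders; gradient
  still reaches earlier stages through the composed fields).
* Per-level networks have separate parameters by default (`share_params`
  flips this), since the levels see different input statistics.

## Similarity

**Local squared correlation.** The windowed baseline is
`1 − mean cc²` with `cc² = (cov² + δ)/(var_w·var_f + δ)` over fully-valid
cubic windows (default 9³ clamped to the grid, δ = 1e-8). The squared
coefficient is invariant to local affine intensity maps — including
contrast inversions, the typical CT/MR relationship — making it a workable
multimodal loss; δ regularises texture-free window pairs to "aligned"
instead of amplifying noise quotients, and by Cauchy–Schwarz cc² ≤ 1 so
the loss is non-negative. δ is deliberately far below the variance
products of informative windows (~1e-6 and larger); a larger δ was
observed to wash out the misalignment penalty for texture-against-flat
windows.

**Learned evaluator.** A channel-reduced 3D residual CNN regresses a
scalar spatial-error score from an image pair. Training data are
manufactured from single volumes: two random spatial transforms K1, K2
(rotation ±3° per axis, translation ±3 voxels, isotropic scale ±8%, plus
a smooth random per-voxel field) give M1 and M2; the regression target is
`mean |M2 − M1|` computed from the *clean* images; the network input is
(M2, dual-morphology(M1) + ε) with ε zero-mean Gaussian noise
(sd 0.05 of the intensity range) and the morphology radius drawn from
{3, 5, 6, 7, 9}. Because the corruption changes appearance but not the
target, the evaluator must learn to measure spatial discrepancy *through*
appearance change. The trained evaluator is exposed as a differentiable
similarity (lower = better); the L1 objective and the scalar target
follow from reading the error image's 1-norm as the supervision signal.

**Dual-structure morphology.** A structuring pair (Ra, Rb), Ra > Rb ≥ 1,
defines the ring ΔR = ball(Ra) − ball(Rb) and an intermediate ball Rc with
radius round((Ra+Rb)/2). The dual opening is `erode(dilate(f, ΔR), Rc)`,
the dual closing its adjoint, and the white/black top-hats the residuals
against f. The glyph conventions are fixed as ⊕ = dilation and ⊙/Θ =
erosion — the only reading that makes the top-hat definitions opening- and
closing-like. Balls are 3D (a slice-wise 2D mode is available), borders
replicate, and ring openings are *not* idempotent (unlike ordinary
openings); nothing assumes they are.

## Training

Loss = similarity + λ · mean squared forward-difference gradient of the
field (diffusion regularisation, default λ = 1; set λ = 0 to drop it).
Deep supervision is on by default: the loss is applied at every cascade
stage on that stage's own representation, so the coarse stages receive a
direct signal; stage weights default to (0.5, 1, 1, 0.5) coarse→fine,
giving the modality-robust enhancement stages the most say. Optimisation
uses Adam with base learning rate 1e-4, kept constant for the first 5000
iterations and multiplied by 0.6 for every further (started) block of
1000 iterations; an optional linear warm-up (off by default, so the
published schedule holds from iteration 0) and per-iteration loss
averaging over a small batch of pairs are available and used by the
desk-scale studies. Training is deterministic under a seed; NaN loss
aborts with a diagnostic. The four stages are trained jointly (sequential
training was considered and left out: joint training lets the fine stages
shape the coarse fields through the composition chain).

## Synthetic phantoms

The phantom generator stands in for the clinical cohort, which is not
public. Each phantom is a body ellipsoid containing bladder-, CTV-,
femur- and intestine-like ellipsoids (geometry jittered per seed),
rendered twice with per-tissue Gaussian intensity tables whose rank
orderings deliberately differ between the pseudo-CT and pseudo-MR (bone
brightest in CT, among the darkest in MR; bladder dark in CT, brightest
in MR), plus rendering noise and mild smoothing. The moving volume is the
pseudo-MR warped by a known field: a Gaussian random field (σ = 8 voxels)
scaled to a maximum magnitude of 10 voxels in-plane (out-of-plane scaled
by the grid aspect), plus a radial bladder-centred expansion of 4 voxels
emulating filling change. These defaults were chosen so that the
*unregistered* mean label overlap of a phantom pair (DSC ≈ 0.67) matches
the unregistered overlap reported for the clinical cohort (≈ 0.68–0.70);
the generative fields are fold-free. The returned ground-truth field is
the generative (forward) field; the field a registration should recover
is its inverse, which equals −u up to O(|u|·|∇u|) for these smooth
fields.

What the phantoms do *not* emulate: real tissue texture, imaging physics
(bias fields, CT beam hardening, MR distortion), sliding interfaces, and
topology changes. Passing the desk-scale studies therefore demonstrates
that the machinery — decomposition, cascade, composition, losses,
evaluator — is correct and trainable, not that clinical-grade accuracy is
achieved.

## Desk-scale study sizes

All validation studies run on a single CPU core:

* Phantom grids are 64×64×16 (divisible by 8 for three dyadic levels and
  by 16 for the patch hierarchy), spacing 1×1×5 mm.
* The tiny cascade uses D = 8, three encoder stages of depth 1, window 4,
  decoder width 16 with two mix convolutions per level, trained with Adam
  (lr 1e-3 at this scale, 50-iteration linear warm-up, loss averaged over
  2 pairs per iteration) for 300 iterations on 32 pairs and evaluated on
  10 held-out pairs. The third encoder stage matters: with only two
  pyramid levels per stage network the receptive field is too small for
  ~10-voxel displacements. The warm-up matters too: Adam's first
  scale-invariant steps otherwise kick the zero-initialised flow heads
  into multi-voxel fields, and a run that drives most samples outside the
  volume lands in a zero-gradient border-clamped state it cannot leave.
  The full 12-layer, four-stage encoder configuration remains the package
  default for `NetConfig()`.
* The evaluator study uses 200 samples on 24×24×12 phantoms from 8
  anatomies, transform magnitudes spread over [0, 1] (spatial-error
  targets span ≈ [0, 0.2]), an 80/20 split, and 10 fixed
  increasing-translation pairs for rank checking.

## Numerical choices

* Fields are stored in voxel units of their own grid; resolution changes
  rescale magnitudes by the grid ratio. Out-of-bounds sampling clamps to
  the border (avoids zero-halo artefacts in losses); the warp gradient
  with respect to the field is zeroed where samples were clamped, matching
  the true (zero) derivative there.
* Jacobian determinants of x + ϕ(x) use central differences at interior
  voxels; the JD ≤ 0 summary is the percentage over interior voxels.
* ASSD surfaces are boundary voxels under 6-connectivity; distances use
  physical spacing and are averaged symmetrically.
* Background cropping is threshold + bounding box, padded to even sides so
  dyadic decompositions stay exact; offsets are returned for re-embedding.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; forward passes, training runs and phantom
  generation are bitwise reproducible.

## Known limitations

* The autodiff engine is single-threaded numpy; it is sized for
  desk-scale grids, not clinical 384×256×32 training.
* No diffeomorphic guarantee: smoothness is encouraged by the diffusion
  penalty and measured by JD ≤ 0, not enforced by construction.
* The evaluator regresses a scalar per pair; a per-voxel error image is a
  possible extension but the scalar is what the loss needs.
* Mutual-information and MIND similarity variants, rigid pre-alignment
  and DICOM ingestion are out of scope.
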