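# Methods

## Problem setting and model

Two unpaired image sets are assumed: an easy domain E (no visible fatty
infiltration) and a hard domain H (moderate/severe infiltration), with the
key structural assumption that the *distribution of ground-truth muscle
shapes is the same in both domains* while the intensity content differs.
Under that assumption an adversarial translator can make H images look like
E images without being forced to move object boundaries, so a mask computed
on the translated image can be transferred to the original image unchanged.

Translation trains a mapping pair F: H→E, G: E→H against per-domain patch
discriminators, minimizing

    w_d·L_adv + w_c·L_c + w_r·L_r + w_i·L_i

with the cycle term L_c (L1 reconstruction of both round trips), the
directional term L_r = E_h r(F(h)−h) + E_e r(e−G(e)) with r(x)=max(0,x),
and the identity term L_i (L1 deviation from identity on the generator's
own target domain). All expectations reduce as a mean over pixels, then
over the batch; this keeps weights comparable across image sizes.
Configurations are written G_{w_r,w_i}; w_d = w_c = 1 throughout.

The directional term encodes the physiology: healthy muscle is darker than
infiltrated muscle in T1-weighted MRI, so removing infiltration may only
darken voxels, and synthesizing it may only brighten them. It is one-sided,
invariant under common additive shifts of input and output, and exactly
zero when the generators respect the monotonicity. The identity term
counterbalances the global darkening pressure L_r would otherwise exert.

**Adversarial form.** The least-squares form (targets 1 real / 0 fake) is
the default; a logarithmic/cross-entropy form is available in
`adversarial_losses(..., form="log")`. Least-squares is what the reference
implementations of cyclic translation use in practice and is markedly more
stable for small models; the printed cross-entropy variant is kept for
completeness.

**Scales.** External images are [0, 1]; generators operate on [−1, 1] with
tanh outputs. L_r and L_i are computed on the internal scale — both are
equivariant under the affine map, so the semantics are unchanged.

## Architectures and the numpy NN core

The networks live in `myoseg.nn`: a deliberately small layer library
(convolution as a sum of per-offset GEMMs, instance norm, ReLU/LeakyReLU/
tanh, nearest-upsampling, average pooling) with hand-written backward
passes and Adam (β₁ = 0.5). Correctness is enforced by tests: convolutions
match `scipy.signal.correlate2d`, smooth stacks match numerical gradients
elementwise, and full networks match in gradient direction (cosine > 0.99;
ReLU kinks preclude elementwise equality under finite differences).
Per-offset GEMMs rather than an im2col patch matrix keep the working set
near the input size, which dominates performance on memory-bandwidth-
limited CPUs.

The generator is the usual residual encoder/transformer/decoder (7×7 stem,
strided-conv downsampling, residual blocks, upsample+conv decoding, tanh);
the discriminator is a patch CNN emitting a score map. Two presets:

| preset | generator | discriminator | images | epochs | lr |
|---|---|---|---|---|---|
| `paper` | 9 blocks, 64 ch, 2 downs | 3 layers, 64 ch | 256², pad 300 | 200 | 2e-4 |
| `tiny`  | 2 blocks, 8 ch, 1 down  | 2 layers, 8 ch  | 64², pad 72   | 20  | 5e-4 |

The full-scale preset keeps the conventional 200 epochs / 2e-4. The tiny
preset exists so the whole pipeline trains in minutes on one CPU; at that
scale 2e-4 demonstrably undertrains (translated infiltration plateaus ~0.13
gray above muscle, which re-splits the downstream mixture), so the tiny
preset uses 5e-4. Training alternates a joint generator update (translation
and identity inputs share one batched forward pass per generator — exact,
since instance norm is per-sample) with per-discriminator updates against a
replay buffer of past fakes. Augmentation: random crops from reflect-padded
images, rotations by multiples of 90°, and flips. Model selection is the
final epoch; training is a pure function of (data, config, seed).

## Segmenters

**GMM (unsupervised).** The body is separated from the background by a
two-class k-means intensity threshold; the largest bright component's
*convex hull* is the foreground (the thigh cross-section is convex, and the
hull survives a broken rim where hole-filling does not). Inside it a
3-component spherical Gaussian mixture is fit by EM (max 100 iterations,
tol 1e-4 on log-likelihood, shared initial variance ((s_max−s_min)/10)²)
from fixed initial means (s_min, s_min + (s_max−s_min)/6, s_max) computed
on the foreground gray range. The muscle mask is the component with the
*middle* converged mean: the three tissue classes are ordered bone/vessels
< muscle < fat, and rank selection is stable where "nearest to the initial
middle center" is not (noise drags s_min well below the bone level, parking
the middle init center next to bone).

**Graph-cut (GC).** Exact s-t min-cut of
E(L) = Σ_p −log P(I_p|L_p) + λ_s Σ_{N4} [L_p≠L_q]·exp(−(I_p−I_q)²/2β)
on the 4-connected grid, after Gaussian smoothing with width σ. P(I|L) is a
per-label 64-bin histogram fitted on annotated training slices, floored at
1e-6 and normalized. β is the mean squared neighbour gradient (the standard
contrast estimator); the "curvature weight" λ_s multiplies a
contrast-sensitive Potts term, the standard probabilistic-GC reading, kept
as an explicit approximation. Max-flow runs on integer capacities
(scipy's solver is int32 internally; capacities are scaled adaptively so
every arc and a bound on the total flow stay below 2³¹, keeping energies
exact to ~1e-9 relative). Exactness is asserted against exhaustive
enumeration on small grids across the whole λ_s grid.

**Shape-prior graph-cut (SPGC).** A per-pixel muscle probability map is the
mean of training masks after moment-based similarity alignment (centroid,
principal-axis angle with the π ambiguity wrapped to ±π/2 and suppressed
for near-isotropic shapes, root-area scale) to the first mask's frame; at
test time it is registered onto the image via the frame of the GMM
initialization mask. Frames are computed on the mask's convex hull — the
initialization mask of infiltrated muscle loses up to half its area to
holes, which would otherwise wreck the scale estimate. The unaries blend
appearance with shape: −log[(1−λ_sp)·P(I|L) + λ_sp·P_shape(L)] with
P_shape(muscle) = p_n + (1−p_n)·prior and P_shape(non-muscle) its
complement, so p_n acts as the neutral floor. λ_sp = 0 reduces exactly to
GC (asserted pixel-for-pixel); λ_sp = 1 with a binary prior and λ_s = 0
returns the thresholded prior. This formulation is an explicit stand-in
for the published shape-prior graph-cut family, not a reimplementation of
any specific variant; moment-based registration in particular replaces
iterative intensity registration (deterministic, dependency-free, adequate
for convex phantoms, and a known fidelity gap on real anatomy).

**CNN.** A small U-Net (instance-norm double-conv blocks, average-pool
downsampling, skip connections) trained with pixelwise binary cross-entropy
plus a least-squares adversarial term from a patch discriminator on
(image, mask) pairs — the pix2pix recipe adapted to binary masks
(adversarial weight 0.05; predictions thresholded at 0.5). Same
augmentation and determinism contract as the translation trainer.

## Evaluation protocol

Dice is 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks. Hyper-parameters
for GC (λ_s ∈ {0.001, 0.002, 0.05, 0.1, 0.2, 0.5}, σ ∈ {1, 2}) and SPGC
(additionally λ_sp ∈ {0.1, 0.2, 0.5, 0.7, 1}, p_n ∈ {0.2, 0.3, 0.4, 0.5})
are chosen by grid search with leave-one-out cross-validation *by subject*:
inside each fold, candidate parameters are scored on every remaining
subject with models trained without that subject, and the held-out subject
is scored once with the winner (ties to the first candidate in grid order).
The CNN uses fourfold cross-validation by subject. DSC aggregates per
subject (mean over its annotated slices — every 4th by default, every slice
in the desk study); distributions over subjects are summarized as median,
linearly interpolated quartiles, min, and max. When translated images are
segmented, the mask is always scored against the *original* ground truth.

## The phantom generator

Each subject draws a jittered geometry (outer-thigh and muscle ellipses,
interior bone disc; jitter 10% relative by default) shared by its slices.
Intensities: background 0.05, bone 0.15, muscle 0.35, fat = infiltration
0.85, plus Gaussian noise (sd 0.03) and clipping. Infiltration discs are
placed only where fully inside the muscle mask until the realized area
fraction is within ±0.05 of the target. Easy subjects draw targets in
[0, 0.02], hard subjects in [0.2, 0.7]. Ground truth is the muscle mask
*including* infiltration; fat/bone/infiltration masks are also returned.
The generator reproduces exactly the two properties the method rests on —
identical shape statistics across domains, infiltration indistinguishable
from fat by gray value — and deliberately not MR physics: no bias fields,
partial-volume effects, texture, fascia, or 3-D continuity, and the blob
spatial statistics are uncalibrated free choices. Passing results on
phantoms therefore demonstrate the mechanism of the method, not clinical
performance.

## The desk-scale study

`myoseg.study.run_desk_study` pins one protocol: 25 easy + 25 hard training
subjects × 4 slices (100 + 100 images, 64²), tiny preset, 20 epochs, one
training per weight configuration (G_{0.5,1} and G_{0,1}), evaluated by GMM
on 24 held-out hard slices (8 unseen subjects × 3) plus 12 held-out easy
slices for the identity effect. All randomness derives from a single seed.
These sizes were chosen as the smallest configuration at which the
translation benefit is comfortably reproducible on one CPU. Typical
outcome: median held-out GMM Dice ≈ 0.74 on original images vs ≈ 0.95 on
translations, directional excess mean r(F(h)−h) around 0.015–0.02 for both
trained configurations versus ≈ 0.18 untrained. The *difference* in
directional excess between w_r = 0.5 and w_r = 0 is real in expectation but
small at this scale once both models have converged, so its sign can
fluctuate between individual runs; the pinned-seed study in the test suite
shows the expected ordering.

## Numerical and degenerate-input choices

- Constant images raise a degenerate-input error in `gmm_init_centers`,
  foreground detection, and `gmm_segment` (fewer distinct values than
  components).
- EM uses `reg_covar = 1e-8` so noiseless phantoms (zero within-class
  variance) converge instead of collapsing.
- Graph-cut ties (equal unaries at λ_s = 0) resolve to the sink side
  (non-muscle); min-cut output is deterministic.
- Histogram likelihood floors (1e-6 before normalization) keep unaries
  finite; the SPGC blend floors at 1e-30 only to guard log 0 for binary
  priors at λ_sp = 1, so the λ_sp = 0 reduction stays exact.
- Masks are {0,1} with 1 = muscle, row-major 0-based indexing throughout;
  PNG I/O is 16-bit (exact to 1/65535), NIfTI is float32.
- Training aborts with a diagnostic on non-finite losses rather than
  continuing silently.

## Known limitations

- The shape-prior and registration components are simplified stand-ins
  (moment alignment, linear prior blend); on real, non-convex, multi-muscle
  anatomy both would need replacement.
- The directional loss is computed over the full image including
  background, the simplest reading; masking it to body regions is untested.
- Per-slice min-max normalization to [0, 1] is assumed for real inputs;
  bias-field correction must happen upstream.
- The tiny preset's adversarial game is deliberately small; mode collapse
  is rare at these sizes but the replay buffer and final-epoch selection
  are the only safeguards.
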