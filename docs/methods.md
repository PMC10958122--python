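# Methods

This note documents the model, every default parameter and its rationale,
the synthetic data used for testing, and the numerical choices.

## 1. Problem setting

Given a video clip `Y` (shape `(T, H, W, 3)`, float in `[0, 1]`) and a
binary hole mask `M` (`(T, H, W)`, `1 = hole`), the inpainter produces
`Ŷ` and the final output composites valid pixels through unchanged:
`Y_final = Y ⊙ (1 − M) + Ŷ ⊙ M`. No clean reference footage is assumed
anywhere; supervision comes from pseudo-ground-truth masks (§3).

## 2. Specular-highlight detection

`specmask.detect_specular_mask` flags a pixel as specular when either

- **absolute rule** — mean intensity `> 0.85` *and* colour saturation
  `(max−min)/max < 0.25`: interface reflection is bright and desaturated; or
- **relative rule** — any channel exceeds `1.5×` its local median over a
  `15 px` window: catches weaker highlights on darker tissue.

Connected components smaller than `5 px` are discarded as sensor noise.
The pipeline then dilates detections with a diamond of radius 1 to close
single-pixel gaps.

## 3. Pseudo-ground-truth masks

The key idea enabling unsupervised training: translate each detected mask
by a fixed per-sequence offset (default `(+0.2·W, 0)` pixels) onto tissue
whose texture *is* observed, and train the model to reconstruct that known
texture. Two variants with different dilation order exist:

- **training**: dilate with an ellipse (semi-axes `(5, 3)`, wider than tall
  because highlights smear horizontally under typical scope motion) →
  translate → remove any overlap with the guard-dilated original mask.
- **evaluation**: translate → remove overlap with the ball-dilated
  (radius 3) original → dilate with the same ellipse.

In **both** variants the final mask is intersected with the complement of
the guard-dilated original (`ball`, radius `3`). Rationale: the guard ring
keeps the dark halo that borders real highlights out of the "known texture"
region; applying it in both variants is required for the invariant that a
pseudo mask covers only originally-valid pixels, which the evaluation
depends on. This is the one place where the two dilation orders would
otherwise diverge in guarantee, so the guard intersection is always last.

For the initialisation training phase, `generate_bezier_random_masks`
draws one random star-convex blob per sequence and moves its centroid
along a cubic Bezier trajectory. The control polygon is shrunk so the
per-frame step never exceeds `0.45×` the blob radius (using the Bezier
derivative bound `|B′| ≤ 3·max|ΔP|`), guaranteeing high consecutive-frame
overlap — temporally smooth occlusions, as a real occluder would produce.

## 4. Generator: spatial–temporal transformer

Pipeline per window of frames: normalise to `[−1, 1]`, compute
`X = Y ⊙ (1 − M)`, stack the mask as a 4th input channel, encode each frame
with three 3×3 convolutions (strides 1, 2, 2 → feature map at 1/4
resolution), run `layers` transformer layers, decode with two
upsample+conv stages and a final `tanh`.

Each transformer layer runs one attention operation per head at its own
patch scale `(r1, r2)`:

1. 1×1 convolutions embed features into query/key/value maps of
   `channels / n_heads` channels each;
2. maps are cut into non-overlapping `r1×r2` patches across *all* frames of
   the window; the similarity of query patch `i` and key patch `j` is the
   scaled dot product `s_ij = (p_i^q · p_j^k) / (r1·r2·c)`;
3. softmax is taken **only over valid patches** — a patch is invalid iff it
   intersects the (downsampled, block-max) hole mask — so holes can never
   leak into their own reconstruction; attention weights of invalid patches
   are exactly 0 and every non-degenerate row sums to 1;
4. the output patch is the weighted sum of value patches,
   `o_i = Σ_j α_ij p_j^v`, folded back into a feature map.

Head outputs are concatenated and fused by two 3×3 convolutions with a
residual connection. If *no* patch in the window is valid (fully masked
input), the attention output degenerates to the value embedding itself so
the forward pass stays finite.

Frame windows: each group of `2n+1` consecutive target frames is generated
conditioned on its neighbours `t−n … t+n` plus distant frames sampled every
`s` frames. Defaults `n = 2`, `s = 10`: neighbours supply correlated
texture, distant frames supply texture occluded for many consecutive
frames.

**Default (full-scale) configuration**: input `288×288`, base channels 64,
transformer channels 256, 8 layers, heads at patch sizes
`(72,72), (36,36), (18,18), (9,9)` (each must divide the 72×72 feature
map). **Desk-scale configuration** (`TransformerConfig.tiny()`): input
`64×64`, base 16, channels 32, 1 layer, heads `(8,8), (4,4)` — small enough
for CPU training in seconds per iteration while exercising every code path.

## 5. Discriminator and losses

The critic is a T-PatchGAN-style stack of four 3D convolutions (5×5
spatial, 3-frame temporal kernels; the last is temporally unpadded, so a
clip of `T` frames yields `T−2` temporal score slices and clips shorter
than 3 frames are rejected). Scores are unbounded reals for hinge losses.

- `L_hole = ‖M ⊙ (Y − Ŷ)‖₁ / ‖M‖₁`, `L_valid` the complement.
- `L_adv = −mean D(composited fake)`.
- `L = 1·L_hole + 1·L_valid + 0.01·L_adv` — the L1 terms carry the
  reconstruction; the small adversarial weight only sharpens texture.
- `L_D = mean ReLU(1 − D(real)) + mean ReLU(1 + D(fake))`.

Training alternates one generator and one discriminator Adam step per
iteration. Two phases: **init** on Bezier random masks (teaches generic
occlusion filling), then **finetune** on pseudo-ground-truth specularity
masks, transferring weights.

**Optimiser defaults**: Adam, lr `1e-4`, betas `(0.0, 0.99)` — standard
GAN settings where momentum is kept off to avoid discriminator
oscillation. The *tiny-overfit* runs in the test suite use lr `2e-3`,
betas `(0.9, 0.99)` with `λ_adv = 0`: without an adversary there is no
oscillation risk, momentum is safe, and a single small clip benefits from
the larger step; with these settings 300 iterations reduce `L_hole` by
~94 %. These are ordinary training-hyperparameter choices for the
no-discriminator regime, not tuned thresholds.

Checkpoints are single `.npz` files carrying all weights, the full Adam
state, the master-seeded RNG bit-generator state and a JSON header, so a
resumed run reproduces an uninterrupted run **bitwise** (verified in the
acceptance suite).

## 6. Baselines

- **Diffusion**: solve the Laplace equation over the hole with Dirichlet
  boundary data (sparse direct solve up to 20 k hole pixels, conjugate
  gradients beyond). Maximally smooth; obeys the maximum principle; exact
  identity outside the hole.
- **Temporal exemplar copy**: greedy onion-peel filling, boundary pixels
  first; each target patch is matched by masked SSD (normalised by overlap
  size) against every fully-valid patch within ±2 frames and an 8 px
  spatial window (widened as a fallback), and unknown pixels are copied
  from the best match. Ties break to the smallest temporal offset, then
  raster order, making the result deterministic.

Expected qualitative ordering, verified on synthetic clips whose occluded
texture is fully visible in a neighbouring frame: exemplar copy beats
diffusion on hole MSE (it can recover true texture; diffusion can only
smooth), and the temporally-conditioned transformer beats its own
single-frame ablation.

## 7. Evaluation metrics

All image metrics are computed **only over the hole region** with frames in
`[0, 255]`: that is where inpainting acts, and valid pixels are identical
by construction. PSNR is capped at 100 dB with an explicit flag (an MSE of
exactly 0 is otherwise undefined); SSIM is the mean over the region of the
full-frame SSIM map (Gaussian window 11, σ = 1.5). Reports average per
frame within each video, then unweighted across videos, so long videos do
not dominate; at most 927 frames per video are scored. Disparity estimates
are scored by RMS, end-point error and Bad3 (strictly `> 3 px`), with
occluded pixels includable, excludable, or evaluated alone.

Relative changes are reported as `100·(orig − inp)/orig` (positive =
inpainting reduced the error), flagged undefined when the original is 0.

## 8. Correspondence and relative pose

ORB keypoints (up to 2000) matched brute-force with Lowe's ratio test at
0.75; dense-flow fields can be converted to grid correspondences as an
alternative source. Pose is estimated in normalised camera coordinates
with a **normalised eight-point essential-matrix solver** inside RANSAC
(Sampson-distance scoring at 1 px, adaptive iteration count at 99.9 %
confidence, refit on the inlier set), followed by the standard four-way
decomposition with a chirality check (triangulated depths positive in both
views).

*Why eight-point rather than five-point*: the minimal five-point solver
requires constructing and solving a tenth-degree polynomial system; the
eight-point solver is a single SVD, numerically transparent, and — inside
RANSAC with Sampson scoring on calibrated coordinates — recovers noiseless
synthetic poses to ~1e-6 degrees and stays under 0.1° with 40 % outliers,
which is far below the effect sizes the harness is meant to detect. The
extra three points per sample are irrelevant at the match counts involved.

Degeneracy: after rotation compensation, the median residual pixel
displacement of the inliers estimates parallax; below `0.5 px` the
translation direction is unobservable (pure rotation) and the estimate is
flagged rather than trusted. Rotation error is the geodesic angle of
`R_est R_gt^T`; translation error is the angle between directions with the
`±t` sign ambiguity folded (anti-parallel scores 0).

Frame pairs are drawn with a moving window, stride 1: pairs `(i, i+20)`
for all `i`; sequences of 20 frames or fewer yield no pairs and an
explicit too-short flag instead of an error.

**Paired Δ-statistics** (`summarize_pose_errors`): per frame pair, the
difference `original − inpainted` of each metric (so positive = the
inpainted video is better for error metrics); summarised by
min/max/mean/p25/median/p75/IQR with linear-interpolation percentiles, plus
the mean per-pair signed relative change in percent (pairs with a zero
original value are dropped from that mean only and nowhere else).

## 9. Synthetic data — realism and limits

`synthdata.generate_clip` renders a reddish multi-octave value-noise
canvas with darker Bezier "vein" curves, warps it with a smooth similarity
motion per frame, and stamps specular highlights: a saturated Gaussian
core inside a disc, a fully saturated inner core, and a multiplicatively
darkened ring (the dark halo around real highlights). The corrupted clip
equals the clean clip exactly wherever the highlight mask is 0 — so hole
metrics have an exact reference. Highlights can jump per frame
(`jump_prob`) to create the "texture visible in a neighbouring frame"
regime, or drift smoothly.

Limits: the motion is a global similarity (no tissue deformation or
occlusion ordering), illumination is constant, and highlight shape is
circular; the clips validate algorithmic properties, not clinical realism.

Two-view scenes place uniform random 3D points at depths 4–9 viewed by a
500 px-focal pinhole pair related by a y-axis rotation and known
translation, retrying until all points project into both views; with zero
noise the projections satisfy the epipolar constraint to machine
precision. Stereo pairs sample the left image at `c + d(r, c)` (bilinear),
registering ground-truth disparity to the right image; negative disparity
is rejected.

## 10. Numerical choices

- **Custom reverse-mode autodiff** (`autodiff.py`): the environment
  provides no deep-learning framework, so a small `Tensor` engine with
  topological-order backward implements exactly the ops the model needs.
  conv2d/conv3d use im2col via `sliding_window_view` with a hand-written
  scatter-add col2im backward; gradients are verified against central
  finite differences to ~1e-9 relative error.
- All randomness flows through seeded `numpy.random.Generator` instances;
  one master seed per training run derives weight-init seeds via
  `SeedSequence`, and the generator's bit-generator state is serialised in
  checkpoints for bitwise resume.
- Masked softmax subtracts the row max over *valid* entries before
  exponentiation; fully-invalid rows short-circuit instead of dividing
  by zero.
- Video container extraction uses imageio and raises a clear
  `RuntimeError` naming the missing backend when no codec is available,
  rather than failing deep inside a plugin.
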