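# Methods

This note documents the models, numerical choices and limitations behind
`crowngen`. Sizes, defaults and design decisions recorded here are the
package's own; every number quoted is computed by the test suite or
`scripts/acceptance.py`.

## Depth-map codec

A standardized tooth surface is projected along −z onto a regular grid.
The pixel–distance mapping

    pixel = round(255 (h^α − d^α) / h^α),   d ∈ [0, h]

uses visual distance h = 6 mm by default; surface farther than h from the
reference plane, and background, encode as 0. Choices the mapping itself
does not fix:

- **Reference plane.** Anchored at the global z-maximum of the standardized
  mesh (the highest cusp has d = 0), so the 6 mm window always covers the
  occlusal relief of a molar-sized tooth.
- **Rounding.** Half-away-from-zero to integer levels. The inverse map
  d = h·(1 − p/255)^(1/α) inverts the un-rounded forward map, so round-trip
  error is bounded by the largest depth gap between adjacent levels. That
  bound is computed by brute force over all 256 levels
  (`quantization_bound`); at α = 2 it is 0.37 mm at 0.1 mm/px settings for
  the far end of the window and ~0.02 mm near the plane — α > 1 spends
  levels on the near (occlusal) side, which is the point of the
  enhancement factor.
- **α selection.** Exhaustive entropy argmax over a candidate list, ties
  toward the smaller α. Entropy is the Shannon entropy of the full 256-bin
  level histogram including background.

**Pose standardization** aligns principal axes (largest spread → x,
smallest → z) via the eigendecomposition of the vertex covariance; the x
sign is pinned by the third moment of the x-projection, the z sign by
rendering both orientations at 32×32 and keeping the one with higher image
entropy (the cusped side carries more information than the smooth
underside), and y completes the right-handed frame. The transform is rigid.
This is idempotent to 1e−9 mm and recovers arbitrary rotations to 1e−6 mm
provided the covariance eigenvalues are distinct — the synthetic crowns are
made slightly elliptical (1.05/0.92 axis ratio) partly for this reason.

**Reconstruction** back-projects every foreground pixel and triangulates by
region growth: a 2×2 pixel cell becomes two triangles only if all four
pixels are foreground and the in-cell depth spread is below a discontinuity
threshold (default 0.5 mm, appropriate for ~0.1 mm/px rendering). Level 0 is
indistinguishable from background by construction; surfaces near the far
plane are therefore not reconstructable, which is a property of the
encoding, not a defect of the mesher.

## Synthetic molar generator

The generator stands in for a private clinical dataset and emulates its
structure, not its anatomy. One case comprises:

- a **target crown**: an elliptical dome (flattish-top radial profile
  `base_height·(1 − ρ⁶)`) carrying 4 or 5 Gaussian cusps on a ring at
  0.55 of the crown radius, offset so the central groove passes between
  cusps; a groove valley of seeded sinuous path is subtracted, tapered to
  zero at the rim. Defaults: diameter 10 mm, base 3.5 mm, cusps ~1.5 mm,
  groove depth 0.7 mm — total relief under the 6 mm window;
- two **adjacent crowns** (same family, 0.92/0.95 diameter) at ±1.08
  diameters along x;
- an **opposing crown** mirrored above the target with a seeded minimum
  inter-jaw gap drawn from U(0.02, 0.10) mm;
- the **preparation**, produced by clipping the target crown at a margin
  height (default 0.5 of the crown's maximum height);
- masks: the **defect** (pixels whose rendered height changed when
  carving — computed from the two z-buffers, which guarantees bit-exact
  agreement between preparation and target outside the defect), the
  **groove** region (within one groove-width of the groove path), and the
  **occlusal fingerprint** (pixels with inter-jaw gap below 0.15 mm; the
  threshold is a config knob since contact marking in practice is an
  operator convention);
- the **gap-distance field**, clipped to [0, h] and normalized by h.

Local crops are the 10 %-padded square bounding box of the defect,
resampled to the local size by nearest-neighbour index maps (kept with the
case so the crop is exactly invertible for gradient scatter during
training).

Everything derives from `numpy.random.default_rng(seed)`; identical seeds
give byte-identical meshes, images and PNG files. What the generator does
**not** emulate: real enamel texture, scanner noise, undercuts (crowns are
single-valued height fields by design — the pipeline only ever consumes the
occlusal projection), patient-level shape statistics, or dentist-marked
fingerprints. Green tests on this data therefore demonstrate the
correctness and trainability of the machinery, not clinical performance.

## Networks

`crowngen.nn` is a compact NumPy layer library (strided/dilated/transposed
convolution via im2col, batch norm, dense, LeakyReLU, sigmoid, Adam) with
exact reverse-mode gradients, verified against central finite differences
in the test suite. Everything runs in float32 on one CPU and is
deterministic.

**Generator** (4 conditioning channels → 1 surface channel): stem conv,
two stride-2 convs (bottleneck at 1/4 resolution), four serial dilated
blocks at rates (1, 2, 4, 8) — each block Conv-BN-LeakyReLU — whose four
outputs are concatenated channel-wise and fused by a 1×1 conv, then two
4×4 stride-2 transposed convs and a 1×1 sigmoid head. The serial stack has
a 31-pixel theoretical receptive field at kernel 3 (1 + Σ rᵢ(k−1)),
confirmed by impulse response. Rates are powers of two, the established
convention for exponential receptive-field growth. The output is composited
as `gen·mask + input·(1−mask)`, so pixels outside the defect are untouched
by construction. Channel widths default to 64→128→256 at full size and are
configurable; all activations use LeakyReLU slope 0.2.

**Discriminators.** Global branch: 5×5 stride-2 convs (depth scales with
image size: four layers at 64×64), flatten, dense feature vector. Local
branch: exactly five convs plus a fully connected layer. Each branch has a
per-branch sigmoid head; a fusion head concatenates both feature vectors
into one probability. Per-branch adversarial training (the sum over the two
discriminator objectives) is the default; fused-probability training is a
config switch, since either wiring is defensible. The generator uses the
non-saturating −log D(fake) form rather than the literal min-max, the
standard remedy for vanishing early-training gradients.

## Losses and schedule

L_total = L_adv + 100·L1 + 50·MSE + 50·perceptual. The perceptual features
come from the frozen global-discriminator trunk (per-layer mean-L1 over
LeakyReLU outputs, each normalized by its own C·H·W); this keeps the
package free of external pretrained weights, and any feature-net callable
can be substituted. During perceptual evaluation batch norm uses its
running statistics as a fixed affine map, so the discriminator is never
perturbed by the generator's pass.

Stages: (I) generator alone minimizes 100·L1 plus two masked-L1 constraint
terms — on the fingerprint mask (occlusion consistency) and the groove mask
(biological morphology) — both weight 1.0; (II) the generator is frozen
(bit-identity asserted) while both discriminators train from scratch
against it, with MSE/perceptual logged for monitoring (a literal
"discriminators minimize MSE" reading is not a trainable objective; a
`stage2_literal` flag folds those terms into the reported Stage-II
objective for completeness); (III) joint training, alternating one
discriminator and one generator update per batch. Divergence (NaN or loss
above 1e4) aborts with the last stage checkpoint retained.

Per-iteration logs record L1, MSE, perceptual, the generator's adversarial
term, and the dual-discriminator adversarial objective. At GAN equilibrium
the generator's non-saturating term sits at 2·log 2 and the discriminator
objective at 2·log 4; the scaled study reproduces both plateaus. The
trajectory checks therefore read "the adversarial loss decreases" against
the discriminators' objective over its own from-scratch training window,
and the pixel/feature losses over the generator's updates.

## Metrics

- **PSNR**: 10·log₁₀(peak²/MSE), peak 255 on 8-bit maps (configurable);
  identical images return a documented 100 dB cap with a flag.
- **SSIM**: scikit-image with the original convention (11×11 Gaussian
  window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, population covariance).
- **FSIM**: implemented from its definition — log-Gabor phase congruency
  (4 scales from wavelength 6 at multiplier 2, 4 orientations, σ_r = 0.55)
  and Scharr gradient magnitude, combined as S_PC·S_G with constants
  T₁ = 0.85, T₂ = 160 and averaged under max-PC weighting. The noise
  compensation of the full phase-congruency estimator is omitted (T = 0
  with a small ε); for clean synthetic imagery this changes values only
  marginally and keeps the implementation dependency-free and exact at
  identity (FSIM(a,a) = 1).
- **Surface deviation**: signed point-to-surface distances from every
  generated-mesh vertex to the target surface; SD is their standard
  deviation, RMS their root mean square. No re-registration is applied —
  the shared standardized frame (with adjacent teeth) already registers the
  meshes; optional rigid ICP exists but is off by default. Closest points
  use a KD-tree over triangle centroids (16 candidates) with exact
  point–triangle projection, exact for meshes whose triangles are small
  against feature spacing, which holds for all rasterized height fields
  here. `crown_deviation` restricts both depth maps to the synthesized
  crown region before reconstruction and scales the discontinuity threshold
  with pixel pitch (max(0.5 mm, 4·mm/px)): at coarse scene resolutions,
  whole-scene comparison is dominated by steep inter-tooth valleys that are
  legitimately unmeshable, which says nothing about the crown.

## Scaled study conditions

The staged-training study runs 60 cases at 64×64 (32×32 local crops),
split 48/6/6, stages 5+5+10 epochs, batch 4, generator base width 8,
discriminator width 8 with 64-d features — sizes chosen so a full study is
about a minute on one CPU while leaving the qualitative stage-ordering
behaviour intact (supervised Stage I already reaches high PSNR on this
clean data; Stage III adds several dB on top). The acceptance script
reports the stage-I and stage-III test-split means and the RMS crown
deviation computed through the full image→mesh path.

## Known limitations

- Height-field-only geometry: no undercuts, no closed crowns, no margins
  fit to a die; export is the occlusal shell.
- The rasterizer assumes the occlusal view is single-valued; arbitrary
  meshes are handled by the z-max rule, which silently drops undercut
  geometry.
- Depth values within one quantization step of the far plane are lost to
  background; deviation metrics exclude such pixels implicitly.
- The discriminators are deliberately small; at these data sizes a strong
  discriminator would overfit 48 training cases long before the generator
  benefits.
- FSIM omits phase-congruency noise compensation (see above), so absolute
  values on noisy natural images may differ slightly from reference
  implementations; orderings are preserved in the cases tested.
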