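# crowngen

Automated design of the occlusal (chewing) surface for a prepared mandibular
first molar. When a dentist grinds a damaged tooth down to a preparation, the
missing crown surface must be designed so that it meets the opposing tooth
correctly, blends with its neighbours, and carries the biological morphology
of a natural molar — cusps, a central groove, and the occlusal fingerprint
(the pattern of contact patches with the antagonist). `crowngen` treats this
as a conditional image-inpainting problem on depth maps and provides the full
chain: geometry encoding, a trainable adversarial inpainting network, and
quantitative evaluation — exercised end-to-end on a seeded synthetic molar
generator, so every result in this repository is reproducible from an integer
seed.

## Method

**Depth-map encoding.** A pose-standardized tooth mesh (occlusal direction
along +z) is orthographically projected onto a pixel grid. Distance d (mm)
from the reference plane maps to an 8-bit level

    pixel = round(255 · (h^α − d^α) / h^α),   0 ≤ d ≤ h,

with visual distance h = 6 mm and enhancement factor α; surface beyond h
(and empty background) encodes as 0. The mapping is invertible up to
quantization, so generated images convert back into 3D surfaces. α is chosen
by maximizing the Shannon entropy H = −Σ_t P_t log₂ P_t of the rendered
image.

**Network.** A single generator G takes the conditioning stack
(x₁ preparation-with-neighbours, c₁ opposing tooth, c₂ fingerprint ∪ groove
mask, d inter-jaw gap field), downsamples twice by strided convolution to 1/4
resolution, runs four serial dilated Conv-BN-LeakyReLU blocks (rates 1, 2,
4, 8) whose feature maps are concatenated channel-wise and fused, upsamples
by transposed convolutions, and emits a sigmoid-normalized surface image
composited into the defect region only. Two discriminators judge the result:
a global branch (5×5 stride-2 convolutions) over the whole scene and a local
branch (five convolutions + a fully connected layer) over the defect crop,
fused by feature concatenation into a real/fake probability; the adversarial
objective sums the two branch objectives,
min_G max_{D_G,D_L} Σ_k L_GAN(G, D_k).

**Objective and schedule.** The generator minimizes

    L_total = L_adv + λ_L1·L_L1 + λ_mse·L_mse + λ_per·L_per

with λ_L1 = 100, λ_mse = 50, λ_per = 50, Adam(lr = 2·10⁻⁴, β₁ = 0.5,
β₂ = 0.999), LeakyReLU slope 0.2. Training complexity grows in three
stages: (I) generator alone with L1 plus masked occlusion/morphology
constraints, (II) generator frozen while both discriminators train from
scratch, (III) joint adversarial training on the full objective.

Evaluation uses PSNR, SSIM, FSIM (phase-congruency × gradient similarity)
and the SD/RMS of signed point-to-surface distances between the generated
and target crown meshes.

All network layers, backpropagation and the Adam optimizer are implemented
in NumPy inside `crowngen.nn` — no deep-learning framework is required, and
runs are bit-reproducible on CPU.

## Worked example

```python
import numpy as np
from crowngen import (
    CrownParams, DepthEncoding, generate_crown, project_mesh, image_entropy,
    select_alpha, reconstruct_mesh, surface_deviation, quantization_bound,
    depth_to_pixel,
)

crown = generate_crown(CrownParams(n_cusps=4, cusp_height=2.0, seed=7))
print(f"crown mesh: {crown.n_vertices} vertices, {crown.n_faces} faces")

enc = DepthEncoding(alpha=2.0, h=6.0, mm_per_pixel=0.09, width=128, height=128)
print(f"level at d=3 mm: {depth_to_pixel(3.0, enc)}")

alpha = select_alpha(crown, [0.5, 1.0, 2.0, 4.0], enc)
dm = project_mesh(crown, DepthEncoding(alpha=alpha, h=6.0, mm_per_pixel=0.09,
                                       width=128, height=128))
print(f"selected alpha: {alpha}, image entropy: {image_entropy(dm):.3f} bits")

rec = reconstruct_mesh(dm)
sd, rms = surface_deviation(rec, crown)
print(f"codec round trip: RMS {rms:.4f} mm "
      f"(quantization bound {quantization_bound(dm.encoding):.4f} mm)")
```

prints

```
crown mesh: 7576 vertices, 14764 faces
level at d=3 mm: 191
selected alpha: 1.0, image entropy: 5.217 bits
codec round trip: RMS 0.0039 mm (quantization bound 0.0235 mm)
```

The level 191 is the hand-checkable value 255·(36−9)/36 = 191.25 rounded;
the round-trip RMS of 0.004 mm shows the encoding loses only quantization.
For this synthetic crown, entropy peaks at α = 1 (the entropy-argmax rule
adapts α to whatever geometry it is given).

A full run — dataset synthesis, α selection, staged training, inference,
mesh reconstruction and a metric report — is one command:

```bash
crowngen run-all --seed 0 --out runs/demo
```

which writes `runs/demo/metrics.csv` (per-test-case PSNR/FSIM/SSIM and
SD/RMS in mm, with mean ± SD summary rows), `train_log.csv` (per-iteration
L1/MSE/perceptual/adversarial losses) and stage checkpoints. The
`OcclusalInpainter` estimator in `crowngen.estimator` exposes the same model
through the scikit-learn fit/predict API.

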