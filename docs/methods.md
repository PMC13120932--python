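# Methods

## Problem and model

`histomorph` performs binary image-level classification of oral
histopathology tiles (Normal vs oral squamous cell carcinoma, OSCC).  Two
properties of real H&E material drive the design: staining style varies
across laboratories and scanner batches, inviting colour-shortcut learning,
and diagnostic evidence is spatially structured — nuclear morphology and
tissue architecture matter both locally (boundary continuity) and at long
range (similar tumour nests in distant regions).

The model is a pipeline of three parts.

**Token backbone.**  An image `x ∈ R^{H×W×3}` is mapped to token features
`F ∈ R^{N×C}` on a 2-D grid, `N = (H/s)(W/s)` for total stride `s`.  Tokens
correspond one-to-one with grid cells; all downstream spatial structure is
derived from the token coordinates `p_i = (row_i, col_i)` (0-based,
row-major, grid units), never from row order.  The default desk-scale
backbone has stride 8: a 4×4 patch embedding, then 3×3 conv + ReLU + 2×2
average pool, then a final 3×3 conv + ReLU (channels 16/32/32, ≈3·10^4
parameters).  A hierarchical pretrained backbone (e.g. a Swin transformer's
final-stage grid, stride 32, patch 4 / window 7) can be attached through
`CallableBackbone`; it is treated as a fixed feature extractor.

**Stain suppression (SDA).**  Backbone tokens are factorised into

    Fs = MLP_s(F)                  (token-local; one hidden ReLU layer of width C)
    Fm = F + DWConv(WAttn(F))      (residual; window attention + 3×3 depthwise conv)
    α  = sigmoid(F w_α + b_α)      (one scalar per token, computed from raw F)
    F̃  = α ⊙ Fm + (1 − α) ⊙ Fs    (α broadcast across channels)

The stain branch is deliberately unable to mix tokens, so it can model
colour/intensity drift but not structure; the morphology branch mixes only
within attention windows dilated by the conv radius.  The decomposition is
architectural: no auxiliary disentanglement loss is used, and end-to-end
classification loss is the only training signal.  Window attention uses
non-overlapping windows (single head, scaled dot-product).  Grids not
divisible by the window are zero-padded with padded keys masked out of the
softmax — exact, because padded tokens receive zero attention weight, unlike
edge replication which double-counts boundary tokens; a grid smaller than
one window degenerates to a single global window (logged).  The depthwise
conv is zero-initialised so the morphology branch starts as an exact
identity.

**Spatial transformer classifier head (STC).**  Tokens become graph nodes
`h_i^(0) = f̃_i W_f + PE(p_i) W_p` with a fixed 2-D sinusoidal positional
encoding by default (a learnable per-axis table is available).  Topology is
dual: adjacent pairs (`‖p_i − p_j‖₂ ≤ r`, self-loops included) and their
complement.  A content-based structure matrix is estimated **once** from
`h^(0)`: scaled dot-product scores `S = (h⁰W_q)(h⁰W_k)ᵀ/√d` are
softmax-normalised separately on the adjacent and non-adjacent supports
(rows with empty support are all-zero, never NaN), then fused as
`Â = λ Â_adj + (1−λ) Â_non` with `λ = sigmoid(θ)`, `θ` initialised to 0.
Each of the `L` layers applies a graph-transformer step — a fresh full
softmax attention multiplied elementwise by `Â`, then value aggregation —
followed by a dynamic graph convolution `h ← ReLU((Â h_half) W_g) + h`.
The elementwise product in the attention step is **not** renormalised
(faithful to the update as written); a `renormalize` switch restores row
stochasticity for experimentation.  A tanh-bottleneck attention readout
pools the final node states into `z` (a convex combination of node states),
and a linear softmax layer yields the two class probabilities.

Head defaults: `r = 1.5` grid units (8-neighbourhood including diagonals),
`d = 128`, `L = 2`, ReLU, sinusoidal PE.  The `√d` divisor follows the
standard scaled-attention convention.  Whether `λ` should be global or
per-layer is an open design point; a single global scalar is used because
structure estimation happens once, before the layer stack.

## Training protocol

Stratified splitting assigns, per class, `round(0.7 n)` to train,
`round(0.1 n)` to val and the remainder to test (half-up rounding); this
rounding rule reproduces the published per-class split counts of both public
OSCC repositories exactly (203/29/58, 654/93/187, 1051/150/301,
7132/1019/2037).  Class imbalance is handled twice, as in the reference
protocol: batches are class-balanced (each batch draws half its slots per
class, resampling the minority), and the cross-entropy loss carries balanced
inverse-frequency weights `w_c = n_train/(2 n_c)`.  Optimisation is AdamW
(lr 1e-4, weight decay 1e-2 by default), cosine-annealed per epoch, with
global gradient-norm clipping at 1.0; the checkpoint maximising validation
F1 is returned.  All numerics are float64; the `mixed_precision` config flag
is accepted for config compatibility but does not change the arithmetic.
Runs are deterministic given the seed.

## Synthetic data and the shortcut benchmark

The generator emulates the two ingredients the stain-robustness question
needs and nothing else.  Morphology carries the label: normal-like tiles
have 5–10 round nuclei (radius 3.5±0.5 px, boundary irregularity 0.15),
OSCC-like tiles 18–28 irregular nuclei (3.0±0.6 px, irregularity 0.6) on an
eosin-pink textured background; the count ranges are disjoint, so the
rendered nuclei count determines the label by thresholding and a
colour-blind classifier can always solve the task.  Stain style is a
per-channel affine transform in optical-density space (`OD = −log I`,
Beer–Lambert), the space in which real staining variation is approximately
multiplicative; the two default domains are hematoxylin-lean vs eosin-lean
shifts with gains 0.86–1.18, the scale of between-batch drift.  The
confound ρ sets the label–domain correlation within a split (a class's
images land in its "matched" domain with probability `(1+ρ)/2`).  Datasets
are pure functions of (spec, seed); images are quantised to the 8-bit grid
so in-memory arrays and PNG files agree byte-for-byte.

What the generator does **not** emulate: real nuclear chromatin texture,
stromal architecture, magnification effects, focus blur, or within-slide
stain gradients.  Passing behavioural tests on it shows how the
architecture responds to a pure colour confound over a solvable
morphological task — not that it reaches any particular accuracy on real
slides.

The shortcut benchmark (`shortcut_benchmark_config`) trains matched model
pairs — the full model and an SDA-ablated twin — on identical data with
train/val confound ρ = 0.9, and evaluates on a fresh deconfounded (ρ = 0)
test set.  Fixed conditions: 320 train+val images plus 80 test images at
64×64 (≈400 per run), 5 seeds, 12 epochs of AdamW at lr 1e-3, batch 32,
desk-scale model (stride-8 backbone, C = 32, head `d = 32`, window 4 on the
8×8 grid).  These sizes keep a full two-arm, two-condition comparison within
minutes on one CPU while leaving training converged (≈100 % train accuracy).

### Observed behaviour and a known limitation

On this benchmark the *direction-only* claim — that the full model's median
deconfounded test accuracy exceeds the ablated model's — does **not** hold
systematically: per-seed differences go both ways and the medians are
statistically indistinguishable, in both the confounded and the null
(ρ = 0) condition.  The architectural reason is visible in the equations:
the morphology branch is residual (`Fm = F + …`), so the raw
colour-carrying features pass into the fused representation whatever the
gate does, and no loss term forces `Fs` to absorb stain variation.  The
factorisation is therefore not identifiable from the classification loss
alone, and at desk scale gradient descent is free to keep using colour in
either arm.  The corresponding acceptance test states the directional claim
and is expected to fail; the null-control test (arms indistinguishable
without confound) passes.  Users who need stain robustness from this
architecture should consider adding an explicit invariance penalty — which
would be a departure from the reference design.

## Numerical and implementation choices

* All differentiable components run on `histomorph.nn`, a compact numpy
  reverse-mode autodiff engine (ops: broadcast arithmetic, batched matmul,
  common nonlinearities, reductions, reshape/transpose/slice/pad, im2col
  convolution).  Gradients are verified against central finite differences
  in the test suite.
* Masked softmax subtracts the per-row support maximum (detached) before
  exponentiation; empty-support rows return exactly zero.
* Degenerate metric denominators (no positive predictions, single-class
  AUC) return `None`, an explicit undefined marker, rather than 0 — silent
  zeros hide evaluation bugs.  AUC uses the tie-aware Mann–Whitney rank
  statistic, equal to the trapezoidal area under the empirical ROC.
* The gate is zero-initialised (α ≡ 0.5) and λ starts at 0.5, so both
  mixers begin neutral.
* Checkpoints are `.npz` archives of parameter arrays plus a JSON metadata
  blob (model config, selection epoch).

## Limitations

Single attention head throughout; dense `N×N` structure matrices (fine for
token grids up to a few thousand nodes, not for whole-slide scale); no
pretraining (the Swin adapter accepts external features but none ship with
the package); the stain/morphology factorisation is architecturally
motivated but not identifiable, as measured above.
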