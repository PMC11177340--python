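# Methods

`dosecast` predicts 3-D absorbed-dose distributions for pelvic external-beam
radiotherapy from CT and structure masks, and evaluates the predictions with
the standard dosimetric toolbox.  This note records the model, the synthetic
data it is exercised on, the numerical choices, and the limits of what the
tests demonstrate.

## Problem setting

Postoperative cervical-cancer radiotherapy delivers a prescription of 45 Gy
in 25 fractions to a planning target volume (PTV) while limiting dose to
nine organs at risk (OARs).  The package learns the mapping from anatomy
(CT plus binary masks of PTV, bladder, femoral heads, kidneys, marrow,
rectum, spinal cord, and the body contour) to the planned dose field, a
regression from a 33-channel image to a dose image.  A use case of such a
model is locating low-dose regions (for example the 4 Gy isodose surface)
on a *preoperative* scan, e.g. to guide ovarian transposition before
surgery, which makes accuracy in the low-dose bath as important as PTV
coverage.

## Input representation

Per axial slice k, an 11-channel map is built: the CT windowed to
[-1000, +400] HU and rescaled to [0, 1], followed by the ten structure
masks in a fixed channel order (PTV, bladder, femoral head L/R, kidney L/R,
marrow, rectum, spinal cord, body).  Maps of slices k-1, k, k+1 are
concatenated into a 33-channel input (the boundary slice is replicated at
the volume edges), zero-padded to a square grid (512 at clinical scale; 64
in the small configuration used throughout the tests), and paired with the
dose of the center slice k.  Dose grids are resampled to
2.5 x 2.5 x 5.0 mm by trilinear interpolation when needed.  Voxel centers
sit at `origin + index * spacing` with 0-based indices; this convention
fixes the semantics of resampling and of all mm-valued metrics.

Two normalization decisions are recorded in configuration because the
protocol leaves them open: CT is rescaled to [0, 1] after the clip window,
and dose targets are divided by the prescription during optimization (the
prediction is rescaled to Gy and clipped at 0 on output).

The HU windowing is made idempotent by flagging windowed volumes on the
`CTVolume` container; re-windowing a windowed volume is a no-op rather than
a second rescale.

## Network

Encoder — four stages of windowed token attention.  The input plane is cut
into P x P patch tokens (P = 2 small / 4 clinical), linearly embedded to
dimension Ce, and given a learnable position table shared across attention
windows.  Each stage runs a constant-window attention block, a
shifted-window attention block, and a convolutional channel/spatial
attention (CBAM) block; 2x2 patch merging halves the token grid and
doubles the channel dimension between stages.

The attention is a weighted variant of multi-head self-attention: per head,

    Q = x W_Q,  K = x W_K,  V = x W_V
    S = tanh(Q + K) W_alpha / sqrt(dk)
    SA(x) = softmax(S) V

with a learnable `W_alpha` of shape (dk, N_w).  Because `W_alpha` fixes the
token count, attention operates on non-overlapping windows of N_w tokens
(window side 4 tokens by default); patches are tokens and windows group
them.  Shifted blocks cyclically roll the token grid by half a window and
mask attention across wrap boundaries, the standard resolution of
cross-window connection with non-overlapping window computation.  Blocks
are pre-norm residual: `x + Attn(LN(x))` then `x + MLP(LN(x))`.

CBAM applies sigmoid channel weights (shared MLP over global average and
max pooled descriptors) then sigmoid spatial weights (7x7 convolution over
the channel mean/max maps), added back residually: `x + Ms(Mc(x)*x)*(...)`.

Decoder — four stages of bilinear x2 upsampling, skip concatenation with
the matching encoder stage, and two (conv 3x3, batch norm, Mish) blocks at
widths 512/256/128/64 (clinical) or 64/32/16/8 (small).  The deepest three
stages consume encoder skips; the final full-resolution stage takes its
skip from a convolutional stem applied to the 33-channel input, giving the
decoder direct native-resolution access to the CT and the structure masks
(notably the body contour, where the dose field is discontinuous).

Progressive refinement — each decoder stage feeds a generation head (two
conv-BN-Mish blocks and a 1-channel 3x3 conv) emitting a dose map phi_i at
resolutions n/8, n/4, n/2, n.  The pyramid is accumulated coarse-to-fine:

    p_1 = phi_1;   p_i = phi_i + U(p_{i-1}),  i = 2..4

where U is bilinear x2 upsampling, so each branch learns a residual
correction to the upsampled coarser prediction.  (The source formulation
of this recursion is index-inconsistent as printed; the cumulative form
above matches its stated intent of refining from low to high resolution.)

## Loss

Per branch, the fused loss is `L = Lm + Lp + Lr`:

* `Lm = (1/2m) ||p - y||^2` — half mean squared error.
* `Lp` — voxel loss split by the PTV contour: symmetric squared error
  inside the PTV (weight lambda = 0.7), one-sided squared *over*-dose
  `max(p-y, 0)^2` outside (weight mu = 0.3); under-dosing normal tissue is
  never penalized.
* `Lr` — rank loss: the target is sorted ascending, the prediction is
  reordered by the same pixel permutation, and each adjacent pair is scored
  with the logistic likelihood `rho = sigmoid(p*(s+1) - p*(s))` against the
  label `omega` (1 for a strictly increasing target pair, 1/2 for a tie).
  The published complement term reads `(1 - omega)(1 - log rho)`; it is
  treated as a typo for `(1 - omega) log(1 - rho)` (the standard pairwise
  negative log-likelihood the surrounding text names), with the literal
  form available as `rank_variant="as_printed"` for auditability.  Sorting
  is stable, making the loss deterministic under ties, and the loss is
  invariant to joint permutations of (p, y).

Deep supervision sums the fused loss over all four pyramid levels against
area-average-downsampled targets (majority-vote downsampling for the PTV
mask), with equal branch weights by default.  Area averaging is used
because dose is an intensive quantity: it preserves mean dose per region.
Losses are computed over the full padded grid; only *evaluation* is
body-masked.  Rank loss costs O(m log m), so no subsampling is needed even
at 512^2.

## Training

Adam with learning rate 1e-4, weight decay 1e-4, batch 16, 100 epochs is
the clinical-scale default.  The loop is fully seeded (initialization,
batch order; there is no augmentation), uses a constant learning rate by
default (optional cosine decay, linear warmup, and global gradient-norm
clipping are config flags), keeps
the checkpoint with the best validation fused loss (training loss when no
validation set exists), and aborts on non-finite loss.  Checkpoints are
single `.npz` archives holding weights, batch-norm running statistics, and
the serialized configuration.

The numerical stack is a small in-package reverse-mode autodiff engine
over numpy (batched matmul, 2-D convolution via small kernel-offset
einsums, bilinear resampling with exact transpose gradients); gradients
are validated against central finite differences in the unit tests, and
the whole pipeline runs in float32.

## Synthetic phantoms

The generator emulates the statistical and geometric structure of a
postoperative pelvic cohort at desk scale: an elliptical body cylinder
(semi-axes ~55 x 70 mm), a central spherical PTV (~22 mm), eight spherical
OARs in a plausible arrangement, a three-level CT (air -1000 HU, soft
tissue ~0, femoral-head bone ~300, Gaussian texture sigma 30 HU), and a
dose field

    D(v) = Rx * exp(-d(v) / tau) + noise   inside the body,   0 outside,

where d(v) is the Euclidean distance from voxel v to the PTV (so D = Rx
exactly inside the PTV), tau = 15 mm, Rx = 45 Gy, and the noise is
i.i.d. Gaussian (sigma = 1 Gy by default) clipped at 0.  tau = 15 mm
places the 4 Gy isodose about 36 mm outside the PTV — inside the body —
so every case has the broad low-dose bath the low-dose analyses need.
Cohorts jitter body axes, PTV radius, and OAR positions/radii by
independent uniform factors in [0.85, 1.15].

What the phantoms do **not** have: anatomical realism, beam/arc structure,
dose anisotropy, inter-scan deformation, or tissue-density effects.
Passing tests therefore demonstrate that the architecture, losses, and
metrics behave correctly and that the model can fit a smooth dose field
with the right qualitative structure — not clinical-grade accuracy on real
patients.

## Evaluation conventions

* Error metrics (MAE/MSE/RMSE) are restricted to body-contour voxels.
* `Vd` uses >=; `Dq` is the order statistic `sorted_dose[k-1]` with
  `k = floor(n (1 - q/100))` (minimum dose when k = 0), i.e. the largest
  dose received by at least q% of the structure, which guarantees
  `V_{Dq} >= q`.
* Gamma index: 3%/2 mm with global normalization (3% of the maximum of
  the reference dose), 10% low-dose threshold, body-masked.  The search
  is exhaustive over a displacement lattice of step dta/10 within radius
  3 x dta, with linear interpolation of the predicted dose, iterated in
  order of increasing distance with early termination; values at or below
  `max_gamma` (default 2) and the pass rate are exact to the lattice.
  2-D per-slice and 3-D volumetric gamma use the same code path.
* Isodose overlap at a level uses >= membership; DSC and Jaccard obey
  J = D/(2-D); Hausdorff distances are symmetric over surface voxel
  centers in mm, and HD95 is the 95th percentile of the pooled directed
  distance sets.  Empty isodose volumes flag the distances as undefined.
* Plan criteria (bladder V30<50%, V40<40%, V45<35%; rectum V30<60%,
  V40<55%; femoral heads V30<15%; cord Dmax<45 Gy; PTV D95 >= Rx,
  D2 < 1.1 Rx, D98 > 0.95 Rx) are evaluated per structure with missing
  structures marked not evaluable.  The PTV coverage bound is inclusive
  so that an exact synthetic prescription dose passes.

## Problem sizes used in the tests

The default verification configuration is grid 64, patch 2, embedding 32,
4 heads, 4x4-token windows, decoder widths 64/32/16/8 (~1.9 M parameters)
on 8-slice 64x64 phantoms — large enough to exercise every architectural
path (four stages, shifts, merging, skips, all pyramid levels) while
keeping the end-to-end suite runnable on a single CPU.  The end-to-end
probe trains on 4 noise-free phantoms (32 slice samples) with the full
fused loss, batch 8, learning rate 4e-3 under a cosine decay with 30
warmup steps and gradient norm clipped at 5 — the decay anneals the
endpoint wander of such a short run and, with clipping, markedly reduces
run-to-run variance — capped at 500 optimizer steps, and checks that body MAE falls below 5% of the
prescription and that the predicted 4 Gy isodose DSC exceeds 0.8;
reproducibility is checked by comparing metric logs of two identically
seeded short runs.  The clinical-scale configuration (grid 512, widths
512..64) is selectable in `ModelConfig.clinical_scale()` but is not
exercised by the tests.

## Known limitations

* 2-D slice-wise prediction with triplet context only; no true 3-D
  attention along the cranio-caudal axis.
* The rank loss pushes adjacent sorted gaps apart and the one-sided voxel
  term pushes normal-tissue predictions down; with finite optimization
  budgets these terms slow pure-MSE convergence even though the noise-free
  minimizer is the exact fit.
* The gamma implementation reports values above `max_gamma` only as lower
  bounds (pass rates are unaffected).
* Exact positional encoding, head counts, and stage depths of the original
  clinical model are not published; the defaults here are reasonable
  choices, not reproductions.
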