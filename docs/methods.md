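# Methods

## Scope

The package studies a detection-head design — a spatial large-kernel
attention branch plus a pooled multi-head channel-attention branch, fused
additively ahead of parallel classification/regression branches — inside a
deliberately small single-stage detector that trains on one CPU. The
backbone (five stride-2 3×3 convolutions) and neck (1×1 laterals, top-down
2× nearest-neighbour sum, 3×3 smoothing) are plumbing, not contributions:
they exist so the head can be trained and ablated end-to-end. The
evaluation suite is written from first principles and checked in the tests
against an independently coded reference evaluator.

## The head

**Spatial branch.** The chain `1×K → K×1 → 1×K (r=2) → K×1 (r=2)` of
depthwise convolutions has a per-axis effective span of `3K−2` taps. The
input is zero-padded once by the composite margin `(1+r)(K−1)/2` and the
stages then run unpadded, which makes the chain *exactly* one per-channel
correlation with the full-convolution-composed kernel — cascading "same"
padding instead would truncate intermediate values at the boundary and
break that identity. A 1×1 convolution (default fan C→C; a broadcast C→1
variant is selectable) and an activation produce the spatial gate.

- `K` (kernel length, taps): default 11, odd, configurable. With the
  dilated pair this spans 31 feature-map pixels per axis — global at the
  resolutions the pyramid levels have here (4–32 px).
- Gate activation: `sigmoid` by default, keeping the gate in (0,1) so the
  gated output is elementwise bounded by the input (a property the tests
  rely on); `silu` is selectable since the two appear interchangeably in
  descriptions of this kind of module. The choice is recorded in the
  detector config.

**Channel branch.** Global average pooling reduces each channel to a
scalar; a group normalization whitens the descriptor; three per-channel
scale+shift projections produce query/key/value vectors. "Depthwise
convolution" on a pooled `(B, C)` descriptor is read minimally as a 1×1
depthwise kernel on a `(B, C, 1, 1)` view, i.e. exactly per-channel
scale+shift. Heads are the token axis: `(B, C) → (B, h, d)` with
`d = C/h`, attention is `h×h`, which makes `q'k'ᵀ/√d` dimensionally
coherent for a single pooled vector. After attention the output is
reshaped back and passed through an (explicit, here trivial) spatial mean
and a sigmoid to give the per-channel gate.

- `h` (heads): default 4; must divide C.
- `G` (group-norm groups): default the largest divisor of C giving groups
  of ≥ 4 channels, capped at 16. A group of size 1 normalises its entry
  to exactly zero — with many tiny groups the descriptor degenerates and
  the branch stops seeing its input — so very fine groupings are avoided
  by default, while any divisor of C remains configurable. `eps = 1e-5`.

**Prediction.** Both branch outputs are summed and fed to two parallel
branches (3×3 conv + group norm + SiLU + 1×1 predictor each). The group
norm matters for a fair ablation: the attention gates scale features into
(0,1), so without it the dual-perception head would feed its branch convs
at roughly half the activation scale of the plain baseline and train
slower for reasons unrelated to the architecture idea — single-stage
reference frameworks normalise after every head conv for the same reason.
Classification maps have
`A·C_cls` channels, regression maps `A·4` (distances to the four box
sides, decoded as `stride · exp(r)`). The classifier bias starts at −3 so
early training is not dominated by the dense background term. The plain
ablation head is identical minus the two attention branches.

## Detector scaffold

- Strides (8, 16, 32); inputs must be divisible by the largest stride.
- Assignment: a ground truth belongs to the level whose scale range covers
  its longer side (`hi = 8·stride`, last unbounded). Every location inside
  the box on that level is positive; contested locations go to the
  smaller-area box (ties to the lower index); a box left empty-handed gets
  its nearest free location on its level. Deterministic by construction;
  the tests replay the rule exhaustively.
- Loss: `Σ BCE(cls, one-hot) / max(1, P) + Σ_pos (1 − IoU) / max(1, P)`
  with `P` the positive count. The IoU term is computed on decoded boxes
  through the autodiff graph; regression outputs are clamped to ±6 before
  `exp` so gradients stay bounded.
- Decoding: per-class thresholding (default 0.05), clipping to the canvas,
  class-wise greedy NMS (default IoU 0.6, equal scores break toward the
  lower index), top-100 by score.
- Training: AdamW (lr 2e-3, weight decay 1e-4, batch 8) with cosine decay
  to 10% of the initial rate. The budget for the head-ablation experiment
  is 32 epochs on 240 training scenes: convergence was profiled at 6, 16
  and 32 epochs and the loss curves plateau near 32; shorter budgets leave
  both models visibly undertrained, which is the regime where comparing
  head designs is uninformative.
- Serialisation: config + float32 weights in one `.npz`; reload reproduces
  forward outputs bit-exactly.

## Synthetic benchmark

The generator emulates the data regime of bright-field intestinal-organoid
imaging, not its optics: a textured grey background (~0.72 intensity),
organoids as ellipses with a dark rim and brighter lumen, buds as disks on
the body perimeter, Gaussian blur (`blur_sigma`, px) for diffuse
boundaries, additive Gaussian noise, log-uniform radii for scale
variation, rejection sampling keeping pairwise box IoU below
`max_overlap_iou`, and skewed class weights (late organoid rarest by
default) for imbalance. Class is tied to morphology by construction: cyst
and spheroid have zero buds (cyst: thin rim + bright lumen; spheroid:
denser, darker fill), early organoids 1–2, late organoids 3–6. Boxes are
tight bounds of the rendered instance mask, so box regression has an
exact, recomputable target.

What passing tests on this benchmark do *not* show: robustness to real
debris, illumination gradients, focus drift, dense adhesion, or annotation
noise — none of which are modelled. The generator is a controlled
instrument for exercising and ablating the head, not a stand-in for
validation on microscope data.

Every stochastic draw comes from one `numpy.random.default_rng` (PCG64)
per scene, consumed in a fixed order, so scenes are bitwise reproducible;
dataset-level seeds fan out from a global seed through named substreams
(one per module), so adding a consumer never shifts another's stream.

## Evaluation

IoU on half-open pixel boxes; greedy score-ordered matching (each
detection takes the best-IoU unmatched ground truth at or above the
threshold); AP by 101-point right-max interpolation on the
`np.linspace(0, 1, 101)` recall grid (a trapezoidal variant is
flag-selectable); mAP averages the ten thresholds 0.50:0.05:0.95 and all
classes that have ground truth (empty classes are excluded and flagged);
size strata at 32²/96² px² follow the COCO ignore rule (an out-of-stratum
ground truth never counts; detections matching one, or unmatched with
out-of-stratum area, are dropped from the sweep). The confusion matrix
uses class-agnostic greedy matching at configurable IoU/score thresholds
(defaults 0.5/0.3) with an explicit background row and column; zero-support
rows are all-zero and flagged rather than renormalised. Parameter counts
are exact trainable-scalar sums; FLOPs are multiply-accumulates × 2 over
convolutions, projections and attention at a given input size.

## Numerical choices

Computation is float32 (the finite-difference tests run the same graph in
float64). Softmax subtracts the row maximum; BCE uses the
`max(x,0) − xt + log1p(exp(−|x|))` form; group-norm adds `eps` inside the
square root; the IoU denominator adds 1e-9. Scalar constants are injected
as float32 so they never promote a float32 graph. Ties: NMS and matching
break toward the lower index; assignment toward the smaller area then
lower index.

## Known limitations

The backbone is far below the capacity of production detectors, and the
benchmark is synthetic, so absolute metric values here say nothing about
real-world accuracy — only relative statements (head A vs head B under
identical budgets) are meaningful. Multi-anchor decoding (`A > 1`) is
exposed in shapes but the loss/decoder implement the anchor-free `A = 1`
path. The channel branch's attention is over `h` pooled tokens, so its
cost is negligible but its expressiveness is limited to inter-group
structure of the pooled descriptor.
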