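# Methods

## Problem and model

Lung-adenocarcinoma growth patterns (lepidic, acinar, papillary,
micropapillary, solid) are distinguished less by the appearance of
individual tumor cells than by how the cells are organized in space.
`ladgcn` implements a dual-branch classifier built on that observation:

1. **Cell-graph branch.** Nuclei in a tile are represented by their
   centroids and per-nucleus morphology. Nodes are connected by a
   K-nearest-neighbour rule with a distance cutoff: a directed edge
   (i, j) exists iff j is among i's K nearest centroids (Euclidean) and
   D(i, j) < d. The undirected adjacency A is the OR-symmetrization of
   the directed edges. A stack of graph convolutions
   H^(l+1) = σ(D̃^(−1/2)(A + I)D̃^(−1/2) H^(l) W^(l)) propagates node
   features; a permutation-invariant readout (mean by default) and a
   linear map produce the cell-graph embedding h_c.
2. **Semantic branch.** A VGG-style CNN (conv/ReLU/max-pool stages, each
   pool halving the spatial map, then a fully connected layer) encodes
   the whole tile into a semantic vector h_s. The `vgg16` variant emits
   the classical length-1024 vector from 224 px input; the desk-scale
   `vgg_small` default uses 4 conv layers on 64 px input and emits 64
   features.
3. **Fusion.** Each branch is projected by ReLU(W_m h_m) to a common
   width p (default 32). A gating attention score
   z_m = sigmoid(W_{cs→m}[h_c, h_s]) in (0,1)^p scales each projection
   elementwise; the gated vectors are combined by the outer (Kronecker)
   product into a p² tensor capturing multiplicative cross-modal
   interactions, and a single fully connected layer produces class
   logits trained with batch-mean cross-entropy.

An append-1 bilinear variant (which preserves unimodal terms in the
fused tensor) is available behind `FusionConfig(append_one=True)` but is
off by default, since the plain outer product is the reference form.

## Nucleus instances: polar contours and segmentation

Instance contours are encoded as a center plus 36 ray lengths at
10-degree steps; ray k points at angle 10°·k counter-clockwise from the
+x (column) axis in (x, y) = (col, row) geometry. A ray's length is the
distance to the farthest foreground pixel along the ray, sampled every
0.5 px — the farthest-crossing rule makes the encoding robust to mild
non-convexity. Decoding connects the 36 endpoints in angular order into
a closed polygon and rasterizes it. For convex nuclei (ellipses with
semi-axes ≥ 5 px) the encode→decode IoU exceeds 0.90; the regular-36-gon
closed form ½·36·r²·sin 10° is reproduced exactly by the decoded
polygon.

A trained polar-regression detector is out of scope. Two input paths
replace it: ground-truth instance masks (synthetic data), and
`fallback_segment`, a classical segmenter (Otsu threshold on the
grayscale image with nuclei darker, removal of objects under 20 px, and
a watershed on the smoothed distance transform with peak separation
7 px) used at inference time when no masks exist. On well-separated
synthetic nuclei it recovers instance counts exactly; the smoothing
sigma (2 px) suppresses spurious distance-ridge peaks inside elongated
nuclei.

## Node features

Each nucleus contributes 24 features:

* **8 shape**: major/minor axis of the second-moments ellipse (px),
  orientation (rad, [−π/2, π/2)), eccentricity, roundness
  (4πA/P², clipped to 1), area (px²), solidity, perimeter. The
  perimeter is the 4-direction Crofton estimate, which tracks the true
  boundary length of rasterized convex shapes much more closely than
  chain-code contour length (a rasterized disk of radius 20 then scores
  roundness ≈ 0.99 instead of ≈ 0.93).
* **4 GLCM texture**: dissimilarity, homogeneity, angular second moment
  and energy = √ASM, from a symmetric normalized co-occurrence matrix at
  offset 1 averaged over {0°, 45°, 90°, 135°}, after min–max
  quantization of the instance bounding box to 32 gray levels. The
  per-patch quantization range makes the features invariant to constant
  intensity shifts.
* **12 patch descriptor**: the 64×64 window centered on the centroid
  (zero-padded at borders) summarized by per-channel mean/std, four
  grayscale quadrant means and two Haar-like quadrant differences. This
  slot is pluggable — any callable `(image, centroid) → vector` can
  replace it, e.g. a learned self-supervised patch encoder. The default
  deliberately carries a local cell-density signal (nearby nuclei darken
  the window), which is part of what makes the graph branch strong on
  the synthetic classes.

Feature columns are z-scored with statistics fitted on the training
split only and persisted in the checkpoint.

## Graph construction choices

* K defaults to 5; the distance cutoff d defaults to 50 px at the
  synthetic 256 px tile scale. Both are config-exposed.
* The distance test is strict (D < d). Ties at the K-th neighbour are
  broken toward the lower node index via a stable argsort, making graph
  construction fully deterministic.
* KNN excludes the node itself; self-connectivity enters only through
  the +I term of the normalized adjacency, whose diagonal is
  1/(deg+1) and whose leading eigenvalue is 1.
* After symmetrization a hub node can exceed degree 2K (it may be among
  the K nearest of many others); only the directed out-degree is
  bounded by K.

## Training protocol

Two stages, following the branch-then-fuse recipe:

1. Each branch plus a linear head is trained alone with Adam at
   lr 0.001.
2. The fused model fine-tunes the pretrained encoders at lr 1e-5 while
   the freshly initialized fusion head trains at the branch rate
   (two Adam parameter groups). A random-init head cannot move at 1e-5
   within desk-scale epoch budgets; splitting the rates preserves the
   fine-tuning character for the encoders without starving the head.

Desk-scale defaults: batch 16, 30 epochs, 70/15/15 stratified split,
`vgg_small`, GCN widths 24→32→32 with mean readout and a 32-d embedding.
The reference-scale values (batch 64, 100 fine-tune epochs, `vgg16`) are
ordinary config settings. All initialization is Glorot-uniform from
per-component seeds spawned from the run seed; training is bit-for-bit
reproducible on one CPU. Tiles with zero detected nuclei map to a zero
graph embedding rather than crashing.

All tensors/gradients run on an in-package reverse-mode autodiff engine
over float64 NumPy arrays (`ladgcn.autodiff`): dense linear algebra,
3×3 same-padded convolution via im2col, 2×2 max pooling, batched outer
products and a fused softmax cross-entropy. Analytic gradients are
verified against central finite differences to better than 1e-4
relative error through the entire fused model.

## Synthetic data: what it emulates and what it does not

Three point-process classes stand in for growth patterns on 256 px
tiles (three, not five: separating them exercises spatial-structure
learning without requiring real tissue texture):

* `gland` — centroids on rings of radius 30–60 px with angular jitter
  (~16 px arc spacing), echoing gland/acinar lumina; 45 nuclei/tile.
* `sheet` — a contiguous block of a jittered hexagonal lattice with
  12 px spacing (dense solid-like sheets); 80 nuclei/tile.
* `scattered` — a hard-core Poisson process with 25 px minimum
  separation (sparse lepidic-like spread); 25 nuclei/tile.

The counts make mean nearest-neighbour spacing strictly ordered
sheet < gland < scattered. Nuclei are non-overlapping ellipses
(semi-axes 3–7 px, rejection-sampled with at most 1000 attempts each,
1 px clearance so instances stay disjoint and 4-connected) rendered as
dark Gaussian-noise interiors (~110/70/150 RGB) on a bright background
(~225/195/220), loosely hematoxylin-like. Per-tile RNG streams are
derived from (base_seed + global index), so datasets are reproducible
and order-independent.

Not emulated: real H&E stain variation, texture differences between
cell types, nuclear pleomorphism, overlapping/clumped nuclei, and
tissue-level context. Passing the end-to-end test therefore shows that
the architecture can learn spatial organization when it is the
discriminating signal — it does not certify performance on clinical
slides.

## Quantification

A tumor mask (an input; tumor segmentation is out of scope) restricts a
non-overlapping tile grid to tiles with ≥ 50% mask coverage. Each tile
is classified (fallback segmentation builds the graph at inference);
class proportions are rounded to the clinical 5% reporting increments
by largest remainder computed in exact integer arithmetic, so rounded
values are always multiples of 5 summing to exactly 100. Remainder ties
go to the lower class index. The class map colors tiles red, green,
yellow, blue, cyan in class order.

## Evaluation metrics

Per class, one-vs-rest counts give P = TP/(TP+FP), R = TP/(TP+FN),
F1S = 2TP/(2TP+FP+FN) (all reported as percentages); overall accuracy
is micro accuracy trace(C)/ΣC of the confusion matrix C. Vanishing
denominators yield 0 with a warning rather than NaN.

## Known limitations

* The CNN and GCN are desk-scale by default; `vgg16` is provided
  randomly initialized (no pretrained weights are shipped).
* The fallback segmenter assumes dark nuclei on a brighter background
  and will over- or under-split on heavily textured real tissue.
* The patch-descriptor default is handcrafted; swapping in a learned
  encoder changes the feature dimension and requires retraining.
* Graph edges are binary; edge weights or features are not modeled.
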