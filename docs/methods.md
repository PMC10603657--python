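# Methods

## Problem setting

Pixel-level annotation of animal imagery (the motivating case is dairy-goat
instance masks for precision livestock farming) is slow with polygon tools.
Click-based interactive segmentation replaces polygon tracing with a handful
of clicks: *positive* clicks mark the object, *negative* clicks mark
background, and a segmentation network turns clicks plus image into a mask.
The quality of such a model is measured not by a single IoU but by how many
clicks a user needs — the mean number of clicks (mNoC) to reach an IoU
threshold.

This package implements that stack end to end for single-instance samples:
click encoding, click simulation, the segmentation network with its two
decoder extensions, the training regime, and the NoC evaluation protocol,
exercised on a synthetic instance generator so every component is testable
without a proprietary corpus.

## Click encoding

Each polarity's click set S becomes a guidance map

    D(i, j) = min_{s ∈ S} ‖(i, j) − s‖₂ ,

the per-pixel Euclidean distance to the nearest click, computed with the
exact Euclidean distance transform and truncated at 255 (the convention of
the click-encoding literature; the raw definition is unbounded). An empty
set encodes as a map that is 255 everywhere — "no information", and the
natural limit of the definition. Maps are kept unnormalised by default;
dividing by the truncation value is available as a network-input option.
Clicks are single pixels on the unit grid, 0-based (row, col); distances are
in pixel units.

## Click simulation

Training and validation need clicks without users. Let Gp/Gn be the
foreground/background pixel sets, A*/B* the already-placed positive/negative
clicks, and φ(p, S) the shortest Euclidean distance from pixel p to region S
(+∞ for an empty S, so constraints against an empty click set are vacuous).
New clicks are drawn uniformly from the candidate sets

    Cp = { p ∈ Gp | φ(p, Gn) > P1, φ(p, A*) > P2 }
    Cn = { p ∈ Gn | φ(p, Gp) ∈ (N1, N2), φ(p, B*) > N3 }

with strict inequalities exactly as defined. Counts are 1–10 positive and
0–10 negative clicks. The margins are drawn per instance from the pools
P1 ∈ {5,10,15,20}, P2 ∈ {7,10,20}, N1 ∈ {15,40,60}, N2 ∈ {80},
N3 ∈ {10,15,25} (pixels). The candidate set is fully recomputed after every
draw; sampling is seeded and deterministic. If Cp is empty before the first
click the instance is reported unclickable (callers may redraw the margins —
the CLI does, bounded); if a set empties later, the click set is returned
short and flagged truncated.

Design choices that the definition leaves open, resolved here: margins are
drawn once per instance (not per click or per epoch), configurable; clicks
are single pixels, not stamped disks. The candidate machinery is backed by
the exact Euclidean distance transform; the tests verify it against
exhaustive pairwise-distance enumeration, never against itself.

## Network

A DeepLabv3+-family encoder–decoder over a 5-channel input (RGB + the two
guidance maps).

**Encoder.** A backbone tapped at strides 2/4/8/16 with 128, 256 and 728
channels at the three skip taps and 2048 channels into ASPP. Two backbones
honour this contract: a deep aligned-Xception-style network
(depthwise-separable residual blocks: entry flow to 728 channels at stride
8, a configurable middle flow at stride 16, an exit flow to 2048) and a
compact plain-convolution backbone used for CPU-scale work. ASPP runs five
parallel branches — dilated 3×3 convolutions at rates 1, 6, 12, 18 plus
image-level average pooling projected and broadcast back — concatenated and
projected to 256 channels; spatial size is preserved. Skip features are
reduced by 1×1 convolutions to 24/48/144 channels before fusion.

**Decoder.** Three fusion stages walk the pyramid 16×→8×, 8×→4×, 4×→2×.
At each stage:

* **Upsampling attention (UA)**, if enabled, gates the reduced skip
  features: squeeze = global average *and* global max pooling of the
  high-level map S_H (two 1×1×Ch vectors); excitation = a shared two-layer
  bottleneck (FC1: Ch → Ch/r with ReLU, FC2: Ch/r → Cl), applied to both
  vectors, matrix addition, sigmoid → a 1×1×Cl weight vector; scale =
  per-channel multiplication of the low-level map S_L. r defaults to 16
  (per-site hidden width is floored at 1). Weight sharing between the two
  pooled branches follows the channel-attention convention this mechanism
  is modelled on. With all excitation parameters zero the gate is exactly
  sigmoid(0) = 0.5 — a closed form the tests pin down.
* **Multi-head feature fusion (MHFF)**, if enabled, replaces plain fusion:
  two *distinct* 3×3 kernels map the high-level and low-level maps into a
  common 48-channel space, the high-level result is bilinearly upsampled
  2×, both are concatenated (96 channels) and fused by a 3×3 convolution
  back to 48 channels. The block is exactly this five-step procedure with
  plain biased convolutions — no normalisation inside — so it admits a
  literal hand-computed oracle; the decoder applies a ReLU after the block.
  The published procedure's channel symbols are read as "channels of the
  respective input", the only consistent reading.
* With MHFF off, the common baseline applies: bilinear 2× upsample of the
  high-level map, concatenation with the skip, one 3×3 conv-BN-ReLU. The
  baseline also projects to the 48-channel decoder width so the three
  stages chain identically across all four ablation configurations
  (baseline / +MHFF / +UA / both); the canonical single-fusion decoder
  uses a wider head, but a layer-by-layer ladder needs a uniform stage
  width.
* UA precedes MHFF at each site: the attention "guides and screens" the
  skip features that fusion then consumes.

A 3×3 conv-BN-ReLU head, a 1×1 classifier to 2 classes and a final 2×
bilinear upsample produce full-resolution logits; the mask is the softmax
argmax. Two-class softmax with cross-entropy (rather than a one-channel
sigmoid) matches the stated loss. All upsampling is bilinear
(half-pixel-centre convention). Convolutions in ASPP, the reductions and
the backbone carry BatchNorm + ReLU, the standard segmentation recipe.
Inputs must be divisible by 16; inference pads bottom/right to the next
multiple and crops the logits back.

## Numerical substrate

No GPU deep-learning framework is assumed: the model runs on a small
reverse-mode autodiff engine written on numpy (`clickseg.nn`), with
im2col+BLAS convolutions (strided/dilated/depthwise), batch normalisation,
separable bilinear resampling with an exact adjoint, global pooling, fully
connected layers and a softmax cross-entropy head, plus SGD with heavy-ball
momentum. Every operator's gradient is checked against central finite
differences and forward behaviour against scipy convolution oracles in the
test suite. Everything is float32, single CPU, and deterministic given the
seeds — there is no nondeterministic backend.

## Training regime

Per-pixel 2-class cross-entropy; SGD with momentum 0.9; batch size 8
(partial final batch kept); 33 epochs by default, polynomial learning-rate
decay lr(t) = base_lr · (1 − t/T)^power stepped per iteration over the
first 30 epochs, then the last poly value held constant for the final
three. Base LR 0.007 and power 0.9 follow the lineage's conventions (the
regime statement leaves them open); both are configurable and logged.
Images are resized aspect-preserving so the shorter side is 512 (bilinear;
nearest-neighbour for masks, which therefore stay binary) and randomly
cropped to 512×512; crops that lose all foreground are redrawn a bounded
number of times, then accepted. Clicks are re-simulated for every sample
each epoch with freshly drawn margins; a fixed-clicks mode (one centred
positive click) supports controlled overfitting runs. No other
augmentation. A non-finite loss aborts with the learning rate and batch
index.

## Evaluation protocol

Per instance: first click at the interior-most foreground pixel (the
deterministic stand-in for "click the middle of the object"; first-click
placement is otherwise unspecified), then predict → IoU → if below the
threshold, place a corrective click at the interior-most pixel of the
largest 4-connected error component (false negative → positive click, false
positive → negative; ties favour the false negative), up to a cap of 20
clicks. An instance that never reaches the threshold scores NoC = 20.
mNoC@85 / mNoC@90 average the per-instance counts at thresholds 0.85 /
0.90, caps included; the fraction of instances reaching the threshold is
reported alongside. Thresholding is per sample — the only reading
compatible with a per-sample cap. Already-clicked pixels are excluded from
correction placement so a frozen model cannot force a repeated click; ties
in the interior-distance argmax break by raster order. The loop contains no
randomness: two runs with a frozen model are bit-identical. Binarisation is
plain softmax argmax; no post-processing.

## Synthetic data

The generator emulates instance-level crops: one object per sample. Masks
are star-convex blobs — an ellipse of the requested area fraction whose
radius is modulated by random harmonics (orders 2–6) scaled by
`boundary_roughness` — rasterised as a polygon and kept only if a single
4-connected component remains. The image renders distinct low-frequency
textures for foreground and background (default mean contrast 60 intensity
units against noise_sigma 8, so the classes are separable but not trivially
clean) with additive Gaussian noise per channel. Area fractions span the
small-object regime (down to 0.5% of the frame) on demand. Datasets are
written as PNG images, 0/255 PNG masks and a JSON manifest with a
ceil(0.8·n) train split — the rule that reproduces the published corpus
division (3008 → 2407/601) and keeps a lone sample in training.

What the generator does *not* model: occlusion, multiple instances,
photometric realism, background clutter resembling animals, or annotation
noise. Tests that pass on these fixtures therefore establish correctness of
the machinery (encoding, constraint satisfaction, protocol arithmetic,
optimisation behaviour) — not field performance on real imagery.

## Problem sizes used in the checked runs

The bundled verification runs use deliberately small instances so the whole
suite replays quickly on one CPU: oracle equivalence on 200 random maps up
to 64×64; 1000 simulated click sets on blobs of 40–64 px; candidate-set
enumeration on 50 masks of 32×32; the four ablation configurations at full
512×512 resolution with the compact backbone; and an overfit run — 8
synthetic 64×64 instances, a 0.25-width compact model, one centred positive
click, 120 epochs — that reaches per-instance IoU ≥ 0.85 (typically ≥ 0.97)
and mNoC@85 = 1.0 on its training set. The deep backbone is contract-tested
at reduced depth/size; running it at full depth and resolution is a
GPU-scale exercise out of scope here.

## Known limitations

* Headline corpus numbers (mNoC on a real validation set of goat imagery)
  require the original request-only dataset and full-scale training; the
  package reproduces the machinery and its verifiable properties, not those
  values.
* The excitation formula in the source material is typographically garbled;
  the implementation follows the prose (both pooled vectors through the
  shared bottleneck, added, then sigmoid).
* Correction-click placement and first-click placement are unspecified in
  the protocol description; the de-facto standard rules implemented here
  are documented extension points.
* The engine is CPU-only and unoptimised beyond BLAS matmuls; full-size
  Xception training is out of reach by design.
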