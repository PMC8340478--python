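# Methods

## The screening pipeline

`slitscreen` screens for cataract from a slit-lamp sweep video rather than a
single lens photograph. The pipeline is a causal state machine over frames
(no lookahead), with four modes:

* **SEARCHING** — the detector runs on every frame. A single hit moves to
  confirmation; a miss stays here.
* **CONFIRMING** — a second consecutive detector hit is required before the
  pipeline commits, which removes one-frame interference (reflections,
  motion blur). On the confirming hit the pupil bounding box is frozen, the
  Cb gate is calibrated on that frame, and the frame is classified.
* **GATED** — frames are judged by the Cb statistic alone (no detector
  call). Gate 0 (band still in pupil): crop the frozen ROI, classify,
  spend one frame of the window. Gate 1 (band left): revalidate
  immediately without classifying. The window is bounded: after
  `gate_window` (default 5) detector-free frames the pipeline must
  revalidate regardless, so a frozen ROI is never more than 5 frames stale.
* **REVALIDATE** — back through the detector. By default a single hit
  re-freezes the ROI, re-calibrates and classifies (`revalidate_hits = 1`);
  setting it to 2 restores the same two-hit guard as initial entry. With
  the default, a steady in-pupil hold costs 1 detector call per 6 frames.

Classified-frame labels aggregate to the per-eye verdict by majority vote
with ties resolved toward cataract — a screening instrument prefers
sensitivity. A video with no classified frame is `indeterminate` rather
than silently normal.

## The Cb gate

Frames are converted with the full-range ITU-R BT.601 (JPEG) transform, so
gray maps to Cb = Cr = 128 and the full 8-bit scale is used. Over the
frozen ROI:

* `value_cb` — per-pixel Cb; `aver_cb` — its mean;
* `num_cb` — pixels with `value_cb` **strictly** greater than `aver_cb`
  (strict, so a uniform ROI gives 0 and the count is always below the ROI
  pixel count);
* `nor_num_cb` — the current count normalised to unit sum inside the
  two-element window (reference count, current count); an all-zero window
  normalises to zeros rather than raising, since blank/saturated ROIs occur
  in streams;
* gate decision — `d = ReLU(nor_num_cb − reference_nor − τ)`, binarised by
  exact-zero test: `d = 0` ⇒ in pupil (0), else out (1). With the
  two-element window the reference share is 0.5 when the current frame
  matches the calibration frame, so τ (default 0.05, dimensionless) is the
  tolerated excess of the current frame's share.

Why it works physically: the slit source is blue-shifted relative to the
scene, so inside the dark pupil the lit band forms a compact population of
high-Cb pixels well above the ROI mean — a small, stable `num_cb`. When the
band leaves the ROI, the pupil's Cb distribution collapses toward its mean
and roughly half the pixels (noise plus the iris corners of the bounding
box) sit above it — a much larger count. The sign convention (higher
above-mean share ⇒ out of pupil) is a declared modelling assumption; the
tests assert discrimination against ground truth, not a particular sign.
Recalibration at every revalidation keeps the reference current, which also
absorbs the slow growth of `num_cb` as the band slides fully into the box.
`aver_cb` is recomputed per frame (per-pixel statistic of the current
frame), not frozen at calibration.

## Reference detector

A deterministic classical stand-in for a trained neural detector, behind the
same `detect()` contract (pure: identical frames ⇒ identical results):

1. dark-pixel threshold (default 70/255 gray) → connected components;
2. horizontal morphological closing (default 25 columns) bridges the two
   pupil lobes the bright band splits;
3. circularity filter `4πA/P² ≥ 0.6` computed on the component's convex
   hull (the raw outline is jagged after bleaching + closing);
4. the pupil circle (cx, cy, r) is reconstructed from the component's
   vertical extent (the vertical band cannot erode it) and the intact
   horizontal flank — the band's own position says which flank was bleached;
5. the band centre is the sub-pixel centroid of the column-brightness peak
   after a wide median-filter baseline removal (the iris/pupil darkening
   otherwise tilts the centroid sideways);
6. a detection is emitted iff the band centre lies within the pupil's
   horizontal extent; confidence is the fraction of band columns inside it.

All thresholds are constructor parameters; the defaults were chosen on the
synthetic suite. On noise-free phantoms the per-frame agreement with ground
truth is ≥ 99% (residual disagreements are single transition frames where
the sub-pixel band centre and the rasterised pupil edge disagree by under a
pixel).

## Lens classifier

The loss family is implemented as standalone functions: cross entropy
H(p, q) = −Σ pᵢ ln qᵢ (natural log; +∞ flagged, not raised, when q puts zero
mass where p does not); label smoothing p′ = (1−ε)·one_hot + ε·uniform
(ε default 0.1 — the study never states it); its decomposition
H(p′, q) = (1−ε)H(p, q) + εH(u, q) is an executable identity checked to
1e−12; and focal loss −α(1−p_t)^γ ln p_t (α = 0.25, γ = 2 — the standard
defaults for this loss family, also unstated in the study), which
degenerates to cross entropy at γ = 0 and vanishes at p_t = 1. All three
are selectable as the training loss; label smoothing is the default.

The reference network is a miniature densely connected CNN in numpy (manual
backprop, verified against numerical gradients): stem 3×3/stride-2 conv →
avg-pool → dense block (3 layers, growth 4) → 1×1 transition → avg-pool →
dense block → global average pool → linear softmax head. Inside a dense
block each layer consumes the concatenation of the block input and all
previous layer outputs, so an L-layer block carries exactly L(L+1)/2
concatenation edges — the connectivity invariant, not depth, is what is
preserved from the full-size architecture; a full-depth network would add
nothing testable at desk scale. Inputs are 64×64 crops standardised with
fixed constants ((x−0.5)/0.25), so inference is independent of batch
composition.

Training: SGD with Nesterov momentum 0.9 (no dampening), weight decay 1e−4,
batch size configurable (reference 64; 16 in the desk-scale examples,
appropriate for 200-sample sets), initial learning rate 0.01 divided by 10
at the drop epochs. The reference schedule is 300 epochs with drops at 30
and 60; the desk default is 20 epochs with the drop epochs scaled
proportionally (2 and 4). Training is fully seeded: identical data + seed
give an identical loss trace. Checkpoints are single `.npz` files with the
configuration and seed embedded.

## Synthetic eye phantom

What it emulates: a fixed head (constant pupil box within a video — the
premise that lets the pipeline freeze the ROI), a sclera/iris/pupil
concentric-disc geometry, a vertical slit band with a rectangular core and
Gaussian-soft edges (edge σ = 1.5 px), a multiplicative blue-channel gain
inside the lit band (default 1.6, scaled by the band intensity) that makes
the Cb statistic respond to the band, Tyndall scattering of a turbid lens
(a static per-video speckle texture mixed into the pupil region under the
band, amplitude ∝ opacity), and per-channel Gaussian sensor noise
(default σ = 2 intensity units — a realistic sensor level, and necessary:
with zero noise and no iris in the box, an out-of-pupil uniform ROI would
give `num_cb = 0`, aliasing the in-pupil "zero area").

Sweep protocols mirror the four hand-held acquisition habits: A left
sclera → right sclera at constant speed; B the mirror image; C a
uniform-random iris start swept to the opposite sclera; D entry from the
left, reaching the pupil centre and holding for the final 3 s. Videos are
at most 10 s (default 5 s at 20 fps, 160×120 px). The band-in-pupil flag is
true iff the band centre column lies within the pupil's horizontal extent.
Class labels are deterministic in the lens opacity (threshold 0.5); cohort
draws use opacity ~ U(0, 0.15) for normal and U(0.6, 0.95) for cataract
eyes, protocol uniform over {A, B, C, D} per eye.

Determinism: one master seed; the lens texture, protocol draws and each
frame's noise come from independent sub-streams keyed by (seed, tag[,
frame]), so any frame is reproducible in isolation and identical parameters
give bit-identical videos.

What it does **not** emulate — and hence what passing tests do not show
about clinical data: photorealism, corneal reflections, eye movement and
blinking, exposure adaptation, anatomical variation of iris color and pupil
size, and real cataract morphology (nuclear/cortical/posterior subtypes).
The phantom guarantees the *qualitative* Cb separation between
band-in-pupil and band-out frames, not clinically measured magnitudes, and
its two classes are separable by construction; classifier accuracies on it
are a correctness check of the training loop, not an estimate of clinical
performance. The published clinical accuracy (0.94 on 76 private videos)
is therefore not a target of this package's tests.

## Evaluation conventions

Positive class = cataract throughout. Rates with zero denominators are
reported as explicit `undefined`/`None`, never 0. F1 is printed at 4
decimal places in text reports. ROC uses a full threshold sweep (ties share
a threshold) with trapezoidal area, which equals the pairwise rank statistic
with half-credit for ties. The stratified split shuffles within class
(seeded) and applies largest-remainder rounding per class, which partitions
720 + 800 frames at 7:2:1 into exactly (504+560)/(144+160)/(72+80).

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by choice: 20-video
suites (100 frames each, 160×120), 200 training / 60 held-out crops, 20
training epochs. ROI validation requires ≥ 4 pixels; gate τ > 0; protocol D
requires duration > 3 s; ε < 1 for smoothing; dataset fits require ≥ 2
examples per class. Colour conversion rounds half-to-even and clips to
[0, 255]; the RGB↔YCrCb round trip is exact to ±1 level. Verdict ties go to
cataract; equal-score ROC items are handled by the shared-threshold
convention.

## Known limitations

* The gate's sign convention assumes the in-pupil above-mean Cb population
  is the smaller one; scenes where the band brightens the whole ROI (e.g.
  a pupil box much narrower than the band) would need the opposite
  convention or a two-sided margin.
* The reference detector assumes one dark, roughly circular pupil and a
  single dominant vertical band; it is a desk-scale stand-in, not a
  clinical detector.
* Container video decoding depends on the available imageio plugins and is
  excluded from bit-exactness guarantees; numbered PNG sequences are the
  canonical interchange.
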