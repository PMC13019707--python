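# Methods

## Problem and model

Dynamic elastography infers the mechanical state of soft tissue from
induced wave motion. A scanning laser Doppler vibrometer (SLDV) driven at a
single frequency returns a complex-valued surface velocity per scan point:
the real and imaginary parts are the in-phase and quadrature (90°-shifted)
snapshots of the harmonic wavefield. For a homogeneous, isotropic
viscoelastic medium with complex shear modulus μ* = μ′(1 + iη), shear waves
at angular frequency ω = 2πf propagate with complex wavenumber

    k = ω √(ρ / μ*),

so the wavelength λ = 2π/Re k scales as √μ′ and the attenuation is set by
Im k. At f = 350 Hz, η = 0.15, ρ = 1000 kg/m³ the five stiffness classes
μ′ = 1…5 kPa have λ ≈ 2.88, 4.07, 4.99, 5.76, 6.44 mm. The classification
task — binary {1, 5} kPa or five-class {1…5} kPa — is therefore learnable
from the spatial structure of a wavefield patch alone.

The surface response to a point source driven through the sample (a needle
shaker) is modelled as an outgoing cylindrical wave, the zeroth-order
Hankel function H0⁽²⁾(kr) under the e^{+iωt} time convention. With the
principal square root, Im k ≤ 0, and H0⁽²⁾(kr) then decays monotonically
with distance (attenuation plus geometric spreading). The e^{+iωt}/H0⁽²⁾
pairing is deliberate: the opposite pairing (H0⁽¹⁾ with Im k ≤ 0) grows
with distance and is unphysical for a lossy medium. Free-boundary
reflections, Rayleigh–Lamb mode structure and converging axisymmetric
excitation are out of scope; the simulator represents only the diverging
point-source regime.

## Data pipeline

**Patches.** Every training example is a 71×11×2 real array: a 71×11
window of the complex field with channel 0 = Re and channel 1 = Im, then
divided by the sample's maximum absolute value. Per-sample max-abs
normalization removes the arbitrary excitation amplitude so that class
information lives in the spatial pattern, not in μm/s units.

**Synthetic sampling.** A patch's source is drawn uniformly over the area
of an annulus (default 20–40 mm radius) centered on the patch; the annulus
inner radius must exceed the patch half-diagonal (≈17.7 mm at the default
0.5 mm pitch) so the field is singularity-free on the patch. Labels are
0..C−1 in ascending stiffness.

**Fixture scans.** Physical SLDV exports are emulated as text files
(`point_id x y v_re v_im`, one `#` header line) holding a simulated field
on a 79×52 grid at 0.5 mm pitch plus circularly-symmetric complex Gaussian
noise at a configurable per-image SNR (default 20 dB). The fixture source
annulus is 25–45 mm because the full scan footprint has a half-diagonal of
≈23.3 mm. Ingestion interpolates scan points to the regular grid
(piecewise-linear on a Delaunay triangulation, Re and Im independently),
crops a 4-point boundary margin (79×52 → 71×44) and tiles the result into
four non-overlapping 71×11 column strips — hence 13 images per class yield
exactly 52 patches per class.

What the fixtures do **not** emulate: boundary reflections from the
phantom container, Rayleigh–Lamb dispersion, the converging-wave shaker
mode, spatially correlated speckle noise, and frequency-dependent material
drift. Passing the transfer-learning tests on these stand-ins shows the
protocol works when the synthetic-to-"physical" gap is additive noise; it
does not certify performance on real Ecoflex scans.

**Splits.** Stratified per class and seeded: test = ⌊0.2·n⌋, then the
remaining pool splits 70:30 into train and validation (val = round(0.3·
pool)). For n = 52 per class: 29 train / 13 val / 10 test.

**Augmentation.** Offline, training split only, multiplier 4 (each
training sample gains three transformed copies). One random composition
per copy: mirror drawn independently on each axis, integer translation up
to ±2 points (zero-filled), central crop-and-zoom with keep-fraction in
[0.9, 1], and an amplitude gain in [0.7, 1.3] applied to both channels
jointly (the inputs are signed velocity fields, so "brightness" is a
gain, not an offset). Bounds are chosen so no transform can reorder class
wavelengths: zoom rescales apparent wavelength by at most 1/0.9 ≈ 1.11,
strictly less than the smallest adjacent-class wavelength ratio
√(5/4) ≈ 1.118, so the zoomed wavelength intervals of all five classes
remain disjoint.
Mirrors on both axes matter: the hardest patches are those whose source
lies along the short patch axis, and long-axis-only mirroring leaves that
geometry under-represented.

Augmentation is applied to the training split of **both** stages —
synthetic pretraining and physical-format fine-tuning. With only 52 clean
patches per class, the ~5M-parameter dense head can memorize source
positions of individual training patches (training loss → 1e-4 while
held-out accuracy stalls); quadrupling the training split with
label-preserving transforms restores generalization (binary clean
held-out ≈ 1.0, five-class ≈ 0.6, versus 0.80 and 0.42 unaugmented).

## Classifier

One convolutional block and a two-layer dense head:

    input 71×11×2 → conv 3×3 (stride 1, valid) → ReLU → batch norm
    → max-pool 2×2 stride 2 → flatten → dense 1024 → ReLU
    → dropout 0.5 → dense 512 → ReLU → dense C → softmax

Batch normalization uses momentum 0.99 and ε = 1e-3 (the Keras defaults;
looser running statistics measurably stabilize inference after training
with small batches).

Pooling floor-divides odd sizes (69×9 → 34×4); with the default 16 feature
maps the flattened vector has 34·4·16 = 2176 entries and the model
2,755,410 parameters (binary head). The conv width is a free parameter:
16, 32 and 64 feature maps are indistinguishable on validation accuracy
for both tasks, so the default is the smallest. ReLU activations on the
dense layers are the package's choice. Weight init is fan-in-scaled Gaussian (He), seeded; two
builds from the same seed are bit-identical.

The network and its training loop are implemented in numpy (single
precision, hand-written backprop, Adam with a fused update kernel). At
this scale — ~5M parameters, hundreds of training samples — CPU numpy
trains a full protocol in minutes; inference uses running batch-norm
statistics and disabled dropout, so predictions are batch-partition
invariant and repeatable.

## Training protocols

* Binary: binary cross-entropy, Adam, lr 1e-4, batch 10, 30 epochs.
  (With a two-unit softmax, BCE and categorical cross-entropy coincide;
  the loss name records the protocol.)
* Five-class: categorical cross-entropy, Adam, lr 1e-3, batch 16,
  30 epochs.
* Fine-tuning: the conv block (conv weights, batch-norm parameters and
  running statistics) is frozen — bit-identical before and after — the
  softmax classifier (final dense + softmax) is replaced by a freshly
  initialized one, and the dense head trains with the learning rate
  decaying from 1e-3 to 1e-4 over 30 epochs (geometric per-epoch decay;
  linear available), batch 12. Batch norm runs in inference mode during
  fine-tuning so frozen statistics are not perturbed. The optimizer state
  covers only trainable tensors, and backpropagation stops above the
  frozen stage.
* "No fine-tuning" baseline: the same architecture trained from scratch
  on the physical-format set alone with the experiment's training config.
* No early stopping; fixed epoch counts. Fine-tuning epochs default to 30
  (unstated in the protocol's source conditions; matches pretraining).

Per-epoch history records training loss/accuracy accumulated over the
epoch's own minibatches (dropout active, batch statistics — the usual
convention) plus validation loss/accuracy in inference mode.

## Evaluation

All metrics derive from one-vs-rest confusion counts per class i:
recall_i = TP/(TP+FN), precision_i = TP/(TP+FP), macro-F1 = mean of the
per-class harmonic means. Two accuracies are reported: plain
fraction-correct and the macro mean of per-class one-vs-rest accuracies
(TP+TN)/n — identical for binary problems, not in general. Zero
denominators yield 0 and are flagged in the report rather than silently
dropped. ROC curves sweep every unique score plus ±∞ endpoints;
trapezoidal AUC equals the concordant-pair (Mann–Whitney) statistic with
ties counted half, and macro AUC is the unweighted class mean.

The learnability floor is a deliberately trivial physics baseline: a
zero-crossing wavelength estimator. Crossing *rates* along the two grid
axes combine as √(c_row² + c_col²) = 2/λ independently of propagation
direction (a single-axis crossing spacing is not direction-invariant);
each patch is assigned the class with the nearest analytic wavelength in
log space. On clean synthetic data this oracle is near-perfect, so the
CNN is expected to match it there.

## Determinism and seeds

One run seed fans out to per-stage seeds as
`(seed · 1000003 + crc32(stage_name)) mod 2³¹`, so any stage can be
reproduced in isolation. All randomness (source placement, noise, splits,
augmentation draws, weight init, dropout, batch order) flows from these
streams; repeating a run with the same seed reproduces reports
byte-for-byte.

## Problem sizes

The canonical experiments use 52 synthetic patches per class for
pretraining, 13 fixture images (52 patches) per class for the
physical-format stage, 30 epochs everywhere, and augmentation multiplier
4 — the same scale as the study conditions they emulate. The suite's
transfer-learning contrast (fine-tune vs scratch, 5 seeds) runs both arms
on the unaugmented 58-patch physical training split, where the contrast
between a frozen pretrained feature extractor and a from-scratch model of
~5M parameters is most visible and cheap to measure.

## Known limitations

* The Green's-function dialect (pure H0⁽²⁾ surface response) ignores the
  finite phantom thickness; real scans mix guided-mode content.
* Adjacent five-class wavelengths differ by as little as 12%, only just
  above the crop-zoom distortion bound. Five-class clean-synthetic
  held-out accuracy accordingly plateaus near 0.6 (seed-to-seed range
  0.52–0.72) while the zero-crossing oracle reaches ≈0.97 on the same
  splits: the wavelength information is present but this single-block
  architecture at the fixed training budget does not fully extract it.
* Density ρ, scan pitch, scan-grid size and annulus radii are package
  defaults (soft-tissue-like), not measured constants.
* Metrics assume single-label classification; no calibration or
  confidence intervals.
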