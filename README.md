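# vibroelast

Classify the complex shear modulus of soft-tissue-mimicking materials from
scanning-laser-Doppler-vibrometry (SLDV) wavefield images.

Tissue stiffness is a diagnostic biomarker: many pathologies change the
shear modulus of the affected tissue. Dynamic elastography reads it out by
imaging induced wave motion — at a fixed drive frequency, stiffer material
means longer shear wavelength. This package implements that read-out as a
small supervised pipeline for silicone phantom classes spanning
healthy-to-pathological soft-tissue stiffness (shear storage modulus
μ′ = 1…5 kPa, loss ratio μ″/μ′ = 0.15, driven at 350 Hz):

* **wavesim** — analytical wavefield simulator. A homogeneous isotropic
  viscoelastic medium has complex wavenumber k = ω√(ρ/μ*) with
  μ* = μ′(1 + iη); the surface response to a harmonic point source is the
  outgoing cylindrical wave H0⁽²⁾(kr). Training patches (71×11 points,
  Re/Im channels) are sampled with the source placed at random in an
  annulus around the patch.
* **sldv_io** — reads SLDV-style scan exports (plain-text
  `point_id x y v_re v_im` tables), interpolates them to a regular grid,
  crops boundaries (79×52 → 71×44) and tiles each image into four 71×11×2
  patches; also generates physical-like fixture scans (simulated field +
  complex Gaussian noise at a chosen SNR) so the full pipeline runs
  without any measurement data.
* **augment** — offline label-preserving augmentation (mirror, translate,
  crop-zoom, amplitude gain) with bounds that provably cannot reorder the
  class wavelengths.
* **cnn_model / training** — a compact CNN (one 3×3 conv block with ReLU,
  batch norm and 2×2 max-pool, then dense 1024 → dropout 0.5 → dense 512
  → softmax), implemented in numpy with hand-written backprop and Adam,
  plus the transfer-learning protocol: pretrain on synthetic wavefields,
  freeze the conv block, re-initialize the softmax head, fine-tune the
  dense head on physical-format data with a decaying learning rate.
* **metrics** — confusion-matrix metrics (plain and macro one-vs-rest
  accuracy, per-class and macro precision/recall/F1) and one-vs-rest
  ROC/AUC with macro averaging.

See `docs/methods.md` for the model, parameter choices and limitations.

## Worked example

```sh
vibroelast run --protocol binary --seed 7 --out runs/binary7
```

runs the whole binary experiment — simulate 52 synthetic patches per class,
write 13 noisy fixture scans per class, ingest them into 52 patches per
class, split 29/13/10 per class, augment the training splits ×4, pretrain
30 epochs, fine-tune 30 epochs, train the no-fine-tuning baseline, and
evaluate on the held-out test patches. It prints the fine-tuned test
metrics:

```json
{"accuracy": 1.0, "macro_auc": 1.0}
```

i.e. all 20 held-out fixture patches were assigned the correct stiffness
class and the ROC separates the classes perfectly — expected here, because
the fixture stand-ins differ from the pretraining distribution only by
20 dB additive noise, which is far milder than a real
simulation-to-measurement gap. `runs/binary7/report.json` holds the full
report (confusion matrix, per-class precision/recall/F1, per-class AUC)
for the fine-tuned model, the scratch baseline and the synthetic test
split, next to the training histories, the fine-tuned checkpoint, the
fixture scans and the exact config; re-running with the same seed
reproduces every file byte for byte.

The same stages are available individually (`vibroelast simulate`,
`fixtures`, `ingest`, `train`, `finetune`, `evaluate`) for Python-free
orchestration; the library functions accept the same parameters.

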