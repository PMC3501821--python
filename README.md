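# spikeface

A feedforward, cortex-like spiking hierarchy for visual pattern
categorization, exercised on synthetic facial-expression-like images.
The pipeline mimics the ventral visual pathway stage by stage:

1. **Retina** — ON/OFF ganglion cells as a center–surround operator
   `K(x,y) = g·(x²+y²−σ²)/σ⁴ · exp(−(x²+y²)/(2σ²))`, rectified into
   non-negative ON and OFF contrast maps (zero response to uniform light).
2. **V1** — a bank of complex Gabor wavelets
   `ψ_{μ,ν}(z) = (‖k‖²/σ²) e^{−‖k‖²‖z‖²/2σ²} [e^{ik·z} − e^{−σ²/2}]`,
   8 orientations `ψ_μ = πμ/8` per frequency scale `k_ν = k_max/f^ν`; the
   response modulus models complex-cell phase invariance.
3. **Feature learning** — topographic ICA (TICA): prewhitening `z = Vx`,
   maximum-likelihood gradient ascent on
   `L(W) = E[Σ_j P(G_j)] + log|det W|` with neighborhood energies
   `G_j = Σ_i h(i,j)(w_iᵀz)²`, symmetric orthogonalization
   `W ← (WWᵀ)^{−1/2}W` after every step, and mixing recovery
   `A = (WV)⁻¹`.  Components in a neighborhood have dependent energies,
   modelling complex-cell pooling and cortical topography.
4. **Readout** — rank-order spike coding into integrate-and-fire neuronal
   maps: `P(i) = Σ_j mod^{order(j)} w_{j,i}`, one spike per afferent, a
   firing threshold `P ≥ P_th`, one shared-weight map per class trained
   with `Δw_{j,i} = mod^{order(a_j)}/N`, and Gaussian-zone lateral
   inhibition between competing class maps.

Because the decision depends only on the *order* of feature activations,
classification is invariant to any strictly monotone transform of the
feature vector — the central property of rank-order coding.

The package ships a synthetic face generator (five expression classes
defined by mouth curvature, eye openness and brow angle, with optional
lateral illumination and noise), so every stage and the full pipeline are
testable without any external face database.

## Worked example

```sh
$ spikeface make-data faces --n-per-class 10 --seed 42
wrote 50 images under faces

$ spikeface train faces model.npz
{"class_counts": {"anger": 10, "happy": 10, "neutral": 10, "sad": 10, "surprise": 10},
 "thresholds": {"anger": 36.19, "happy": 38.35, "neutral": 41.85, "sad": 37.86, "surprise": 39.41}}
model written to model.npz

$ spikeface evaluate faces --split-seed 0
held-out accuracy: 1.0000
per-class recall:
  anger: 1.0000
  happy: 1.0000
  neutral: 1.0000
  sad: 1.0000
  surprise: 1.0000
```

The thresholds are per-class firing thresholds `P_th`, calibrated as 90 %
of the smallest own-class potential seen in training, so every training
sample fires its own map.  `evaluate` performs a stratified 70/30 split,
trains on the 70 % and reports held-out accuracy, per-class recall and
the confusion matrix.  Per-image scores are available through `predict`:

```sh
$ spikeface predict model.npz faces/happy/happy_000_4363a9c5.png
image_path,predicted_label,raw_anger,raw_happy,...,post_anger,post_happy,...
faces/happy/happy_000_4363a9c5.png,happy,27.47,43.55,...
```

`raw_*` are the postsynaptic potentials of each class map before lateral
inhibition, `post_*` after it; the label is the strongest surviving map
that fired ("rejected" if none fires, e.g. for a black image).

Other subcommands: `fit-tica` (fit the feature stage on a patch matrix
CSV), `dump-bank` (write the Gabor kernels as PNGs), and every pipeline
knob is settable via `--config file.yaml` plus `--set key=value`.

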