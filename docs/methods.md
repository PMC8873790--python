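# Methods

## Pipeline and model assumptions

The decoder treats a 0.4-s, 64-channel EEG window as one sample and
assumes class information is carried by spatio-spectral structure that a
recurrent model can pick up within 64 time steps. Three stages:

1. a bidirectional LSTM with temporal attention maps each segment to a
   small feature vector (the post-softplus activations of its fully
   connected layer);
2. the features' absolute Pearson correlations define a complete weighted
   graph (A = |P| − I) whose symmetric normalized Laplacian
   L = I − D^{−1/2}AD^{−1/2} is rescaled to L̃ = 2L/λ_max − I;
3. a spectral GCN with K-term Chebyshev filters, batch norm, softplus and
   binary-tree max pooling classifies each feature vector as a one-channel
   signal on that graph.

The unnormalized identity "L = D − A" printed alongside the normalized
form holds only for unit-degree regular graphs; this implementation uses
the normalized operator throughout (its spectrum lies in [0, 2], which is
what the λ-rescaling for Chebyshev evaluation assumes), and the test suite
pins both this and the equivalence of polynomial filtering with the
spectral-domain definition y = U gθ(Λ) Uᵀ x.

"Second-order Chebyshev polynomial" is read as polynomial degree 2, i.e.
K = 3 terms (k = 0, 1, 2); K is a configuration knob.

## Parameters that matter

Extractor (`ExtractorConfig`): input size 64 (channels), 64 time steps,
cell size 256, attention size 8, 64 FC features, dropout 0.25 (extractor
only), batch 1024, Adam learning rate 1e-4, L2 coefficient 1e-7. The
training loss is the mean squared Euclidean distance between the softmax
output and the one-hot label ("Euclidean distance" admits several
readings; the squared form on normalized outputs is the one implemented,
with cross-entropy behind `loss="cross_entropy"`). The softmax on the
extractor head is a modelling choice — some normalization is needed for
the distance loss to be meaningful. Forget-gate biases start at 1, other
parameters Glorot-uniform; batch norm uses momentum 0.9, ε = 1e-5, running
statistics at inference. Features are taken from the final epoch's
weights; no early stopping or model selection is applied.

GCN (`GCNConfig`): six layers of 16/32/64/128/256/512 filters, pool 2
each (64 → 1 nodes), K = 3, cross-entropy + 1e-7 L2, batch 16. The stated
Adam learning rate of 1e-7 is kept as the faithful default even though it
is impractically slow on a CPU; scaled-down runs use 1e-3
(`desk_configs`). No dropout in the GCN.

Graph construction defaults to training-partition features only, to avoid
test-set leakage; `graph_data="all"` reproduces the estimate-from-overall-
data variant, with the leakage caveat logged. Zero-variance features get
zero correlation (isolated node) rather than NaN. λ_max comes from a dense
symmetric eigensolve at n = 64 (cheap); the λ_max = 2 shortcut is an
option.

Graclus coarsening visits nodes in a seeded random order, merges by the
normalized-cut score w_ij(1/d_i + 1/d_j) with ties broken toward the
lowest index, and accumulates collapsed intra-cluster weight on the coarse
diagonal (it influences later degrees but is not an edge). Fake nodes pad
singleton chains; their signal entries are held at zero through every
layer (they are re-masked after batch norm + softplus), so a pooled
maximum over a {real, fake} pair always comes from the real child.

## Splits

"10-fold cross-validation" is implemented as ten independent random 90/10
holdouts at the segment level, matching the protocol the evaluation
mirrors; a strict trial-disjoint mode exists because segment-level splits
place segments of one trial on both sides — a known optimistic bias that
is documented rather than silently changed. Rest periods (T0) and baseline
runs are excluded; intervals are half-open with 0-based sample indices.

## Synthetic data

`SynthSpec` emulates the target regime: 64 channels, 160 Hz, 4-s trials,
four balanced classes, 50 trials per class by default. Each class is a
rank-1 spatio-temporal pattern: an orthonormalized random spatial mixing
vector (fixed by a separate pattern seed — a population property, not
noise) times a sinusoid drawn uniformly from a class-specific band
(8–12 / 12–16 / 16–20 / 20–24 Hz), amplitude-modulated by a Tukey(0.1)
raised-cosine envelope with ±20% trial-to-trial amplitude jitter, plus
white or 1/f ("pink", inverse-FFT shaped) noise. `snr` is the linear ratio
of signal RMS to noise RMS; the study conditions use snr 1.

This generator deliberately omits volume conduction (noise is spatially
white), artifacts (blinks, EMG), nonstationarity across trials and
inter-subject variability. Passing tests therefore demonstrate that the
implementation recovers class structure under a controlled
rank-1-per-class regime — not that the architecture reaches any particular
accuracy on real EEG.

## Numerical core

All trainable stages run on a small reverse-mode autodiff engine over
float64 numpy arrays (`migcn.autodiff`): broadcasting arithmetic, batched
matmul, the needed nonlinearities, block max-pooling with argmax routing,
and the fake-padding permutation gather. Correctness is enforced by
central finite-difference gradient checks (1e-4 relative) on random
parameter subsets of both a tiny extractor and a tiny GCN, plus per-op
checks. Softmax subtracts a detached max (shift invariance makes this
gradient-exact); softplus uses log1p-style stable forms. EDF files are
written by a minimal EDF+C writer (16-bit physical/digital calibration,
one annotation channel) and read through mne; round trips are exact to
the format's quantization.

## Problem sizes used in tests and the acceptance script

The end-to-end study runs the full synthetic conditions (2000 segments,
90/10 split) with a reduced model — cell 32, attention 8, 16 FC features,
GCN layers [8, 16] with pools [2, 2], K = 3, Adam 1e-3, 15 epochs per
stage, extractor batch 256, GCN batch 64 — chosen as the package's
single-CPU reference configuration (`desk_configs`); on these conditions
it reaches test GAA ≥ 0.9 with the label-permutation control at chance.
Oracle-equivalence and invariant tests use graphs of 2–24 nodes and
sequences of 2–6 steps, where brute-force references are exact.

## Known limitations

- The faithful GCN learning rate (1e-7) will not converge in reasonable
  desk time; use `desk_configs` or override.
- The extractor processes time steps sequentially in Python; at the
  published scale (cell 256, batch 1024, hundreds of epochs) training is
  GPU-framework territory. The implementation is exact but desk-scaled.
- Micro-averaged one-vs-rest ROC is the default (single curve per
  experiment); macro averaging is available on request in code.
- Segment-level splits share trials between train and test by design of
  the mirrored protocol; use `trial_disjoint=True` for the conservative
  variant.
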