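# migcn — four-class motor-imagery EEG decoding

`migcn` decodes imagined movements (left fist **L**, right fist **R**, both
fists **B**, both feet **F**) from short windows of raw multichannel EEG.
It is aimed at brain–computer-interface researchers who want a
time-resolved decoder: the classification sample is a 0.4-s segment
(64 channels × 64 time steps at 160 Hz), not a whole 4-s trial.

## Method

The pipeline has two trainable stages joined by a correlation graph:

1. **Feature extraction — attention-based BiLSTM.** Each segment is read
   time-major (64 steps of 64-channel vectors) by a forward and a
   time-reversed LSTM cell,

   i(t) = σ(Wxiᵀx(t) + Whiᵀh(t−1) + bi),  f(t), o(t) analogous,
   g(t) = tanh(Wxgᵀx(t) + Whgᵀh(t−1) + bg),
   c(t) = f(t)⊗c(t−1) + i(t)⊗g(t),  y(t) = h(t) = o(t)⊗tanh(c(t)),

   whose per-step outputs are concatenated and pooled over time by a
   learned softmax attention: u(t) = tanh(W_w y(t) + b_w),
   α(t) = softmax(u(t)ᵀu_w), s = Σ α(t) y(t).  A dropout → fully-connected
   → batch-norm → softplus head yields the per-segment feature vector; the
   4-unit softmax output trains the whole stage against a squared-distance
   loss to the one-hot label with an L2 penalty (Adam, 1e-4 by default).

2. **Feature graph.** The features' pairwise Pearson correlations P define
   a complete weighted graph with adjacency A = |P| − I, degree
   D_ii = Σ_j A_ij, normalized Laplacian L = I − D^{−1/2} A D^{−1/2}
   (spectrum in [0, 2]) and the rescaled L̃ = 2L/λ_max − I.  By default
   the graph is estimated from training-partition features only.

3. **Classification — Chebyshev spectral GCN.** Graph convolutions are
   K-term Chebyshev polynomial filters y = Σ_k θ_k T_k(L̃) x (K = 3, i.e.
   second-order, by default), each followed by batch norm, softplus and a
   1-D graph max-pool of size 2 over a Graclus normalized-cut coarsening
   hierarchy (fake zero-degree nodes make every cluster chain a balanced
   binary tree so pooling is contiguous).  Six layers with
   16–512 filters halve the 64 feature nodes down to one, and a softmax
   layer gives the class probabilities (cross-entropy + L2, Adam).

Evaluation follows the repeated-holdout protocol: ten independent random
90/10 splits; global average accuracy (GAA), Cohen's kappa, macro
precision/recall/F1, confusion matrices and micro-averaged one-vs-rest
ROC/AUC per repeat, with medians and quartiles across repeats.

Everything neural runs on a compact reverse-mode autodiff core over numpy
(`migcn.autodiff`), so the package has no deep-learning framework
dependency; gradients are verified against finite differences in the test
suite.

## Worked example

No data download is needed: the synthetic generator emulates the target
regime (64 channels, 160 Hz, 4-s four-class trials with class-specific
band-limited rhythms in noise).

```python
from migcn import (SynthSpec, generate_dataset, make_splits, desk_configs,
                   run_single)

ds = generate_dataset(SynthSpec(n_trials_per_class=50, snr=1.0, seed=7))
ds = make_splits(ds, test_fraction=0.1, n_repeats=1, seed=11)
e_cfg, g_cfg = desk_configs(seed=1)
report, logs = run_single(ds, e_cfg, g_cfg)
print(f"test GAA {report.gaa:.3f}  kappa {report.kappa:.3f}  "
      f"AUC {report.auc:.3f}")
```

This trains the reduced desk-scale model (cell size 32, 16 FC features,
two graph-conv layers) on 1800 training segments and prints

```
test GAA 1.000  kappa 1.000  AUC 1.000
```

i.e. on the synthetic conditions the pipeline recovers the class structure
essentially perfectly: all 200 held-out segments are classified correctly
and the chance-corrected agreement (kappa) is 1.  With labels randomly
permuted before training, the same run stays at chance (GAA ≈ 0.25).

The same flow is scriptable from the shell via the `migcn` CLI
(`synth`, `prepare`, `train-extractor`, `extract-features`, `build-graph`,
`train-gcn`, `evaluate`, `crossval`, `run`); real EDF recordings with
event annotations are read with `load_recording`, using the standard
imagery-run task mapping in `migcn.data.PHYSIONET_RUN_TASK_MAP`.

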