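"""Synthetic motor-imagery-like EEG with class-specific rhythms.

Each task class is emulated as a band-limited oscillation projected onto a
fixed spatial mixing pattern, amplitude-modulated by a raised-cosine-edged
(Tukey) envelope, and buried in white or 1/f noise at a configurable linear
signal-to-noise ratio (RMS signal / RMS noise).  The defaults mirror the
public four-class imagery data regime this pipeline targets: 64 channels,
160 Hz, 4-s trials.  The generator also provides small random graphs with
the same invariants as a Pearson-derived adjacency, used as fixtures for
the spectral operators.

Not emulated: volume-conduction correlations between noise sources, eye or
muscle artifacts, inter-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey

from .data import LABELS, RawRecording, SegmentDataset, build_dataset

#: default oscillation band (Hz) per class, disjoint, mu/beta range
DEFAULT_BANDS = {"L": (8.0, 12.0), "R": (12.0, 16.0), "B": (16.0, 20.0), "F": (20.0, 24.0)}


@dataclass
class SynthSpec:
    """Study conditions for the synthetic four-class imagery generator."""

    n_channels: int = 64
    fs: float = 160.0
    trial_seconds: float = 4.0
    n_trials_per_class: int = 50
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    snr: float = 1.0
    noise_model: str = "pink"  # or "white"
    amplitude_uv: float = 20.0
    pattern_seed: int = 12345  # class spatial patterns are a population property
    seed: int = 0

    def __post_init__(self):
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        for cls, (lo, hi) in self.bands.items():
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(f"band {cls}={lo, hi} outside (0, Nyquist)")
        if self.noise_model not in ("white", "pink"):
            raise ValueError("noise_model must be 'white' or 'pink'")


def class_patterns(spec: SynthSpec) -> np.ndarray:
    """Orthonormalized spatial mixing vectors, one per class (4 x channels)."""
    rng = np.random.default_rng(spec.pattern_seed)
    raw = rng.normal(size=(len(LABELS), spec.n_channels))
    q, _ = np.linalg.qr(raw.T)  # orthogonal class topographies
    return q.T[: len(LABELS)]


def _pink_noise(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """1/f-amplitude noise by inverse-FFT spectral shaping, unit RMS."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    amp[0] = 0.0
    spec = amp * np.exp(2j * np.pi * rng.random(shape[:-1] + (len(freqs),)))
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt((x**2).mean(axis=-1, keepdims=True))
    return x / rms


def _trial_signal(spec: SynthSpec, label: str, rng: np.random.Generator) -> np.ndarray:
    """One noiseless trial: pattern ⊗ enveloped band-limited oscillation."""
    n = int(round(spec.trial_seconds * spec.fs))
    t = np.arange(n) / spec.fs
    lo, hi = spec.bands[label]
    f0 = rng.uniform(lo, hi)
    phase = rng.uniform(0, 2 * np.pi)
    envelope = tukey(n, alpha=0.1)  # raised-cosine ramps at trial edges
    osc = np.sin(2 * np.pi * f0 * t + phase) * envelope
    osc *= rng.uniform(0.8, 1.2)  # trial-to-trial amplitude variability
    pattern = class_patterns(spec)[LABELS.index(label)]
    return np.outer(pattern, osc)


def generate_recording(spec: SynthSpec) -> RawRecording:
    """One continuous recording containing all trials in shuffled order.

    Annotation codes are the task letters themselves; the identity code map
    ``{"L": "L", ...}`` makes it directly consumable by trial extraction.
    """
    rng = np.random.default_rng(spec.seed)
    order = np.repeat(np.arange(len(LABELS)), spec.n_trials_per_class)
    rng.shuffle(order)
    n_trial = int(round(spec.trial_seconds * spec.fs))
    n_total = n_trial * len(order)
    signal = np.zeros((spec.n_channels, n_total))
    annotations = []
    for k, ci in enumerate(order):
        label = LABELS[ci]
        clean = _trial_signal(spec, label, rng)
        if spec.noise_model == "pink":
            noise = _pink_noise(rng, (spec.n_channels, n_trial), spec.fs)
        else:
            noise = rng.standard_normal((spec.n_channels, n_trial))
            noise /= np.sqrt((noise**2).mean(axis=-1, keepdims=True))
        sig_rms = np.sqrt((clean**2).mean()) or 1.0
        if spec.snr == 0:
            trial = noise
        else:
            trial = clean + noise * (sig_rms / spec.snr)
        signal[:, k * n_trial : (k + 1) * n_trial] = trial * spec.amplitude_uv
        annotations.append((k * n_trial / spec.fs, spec.trial_seconds, label))
    names = [f"CH{c:03d}" for c in range(spec.n_channels)]
    return RawRecording(
        signal, spec.fs, names, annotations, subject_id="SYN", run_id=0
    )


IDENTITY_CODE_MAP = {c: c for c in LABELS}


def generate_dataset(
    spec: SynthSpec,
    segment_seconds: float = 0.4,
    stride_seconds: float | None = None,
) -> SegmentDataset:
    """Full synthetic dataset: generate, extract trials, slice into segments."""
    rec = generate_recording(spec)
    return build_dataset(
        [rec],
        run_task_map=IDENTITY_CODE_MAP,
        trial_seconds=spec.trial_seconds,
        segment_seconds=segment_seconds,
        stride_seconds=stride_seconds,
    )


def generate_random_graph(n_nodes: int, seed: int = 0) -> np.ndarray:
    """Random symmetric weight matrix in [0,1] with zero diagonal.

    Shares the structural invariants of an absolute-Pearson adjacency
    |P| − I, so it exercises the Laplacian and coarsening operators.
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    rng = np.random.default_rng(seed)
    w = rng.random((n_nodes, n_nodes))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w
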