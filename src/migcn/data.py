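"""EEG trial extraction, 0.4-s segmentation and train/test splitting.

A recording is a channels x samples matrix with event annotations marking
4-s imagery trials (left fist L, right fist R, both fists B, both feet F).
Each trial is sliced into short windows — by default non-overlapping 0.4-s
segments, i.e. 64 channels x 64 time steps at 160 Hz — which are the
classification samples.  Splits are repeated random holdouts at the segment
level (the protocol of the source dataset's published use); a trial-disjoint
mode is available to keep all segments of a trial on one side.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .edf import read_edf

logger = logging.getLogger(__name__)

#: canonical class order; indices 0..3 are used everywhere downstream
LABELS = ("L", "R", "B", "F")
LABEL_TO_INDEX = {c: i for i, c in enumerate(LABELS)}

#: run -> annotation-code -> task map for the PhysioNet motor imagery
#: protocol (imagery runs only; baseline and executed-movement runs absent).
#: T0 is the between-trial rest period and is excluded.
PHYSIONET_RUN_TASK_MAP: dict[int, dict[str, str]] = {
    **{r: {"T0": "rest", "T1": "L", "T2": "R"} for r in (4, 8, 12)},
    **{r: {"T0": "rest", "T1": "B", "T2": "F"} for r in (6, 10, 14)},
}


@dataclass
class RawRecording:
    """One EDF recording: microvolt signal plus its event annotations."""

    signal: np.ndarray  # channels x samples, µV
    fs: float
    channel_names: list[str]
    annotations: list[tuple[float, float, str]]  # (onset s, duration s, code)
    subject_id: str = ""
    run_id: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError("one channel name per signal row required")
        onsets = [a[0] for a in self.annotations]
        if onsets != sorted(onsets):
            raise ValueError("annotation onsets must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class TrialEvent:
    label: str  # one of LABELS
    onset_sample: int
    n_samples: int


@dataclass
class Segment:
    data: np.ndarray  # channels x timesteps
    label: int  # class index 0..3
    subject_id: str = ""
    trial_id: int = 0
    segment_index: int = 0


@dataclass
class SegmentDataset:
    """Columnar container for all segments plus repeated-holdout masks."""

    data: np.ndarray  # n x channels x timesteps
    labels: np.ndarray  # n, int class indices
    subject_ids: np.ndarray  # n, str
    trial_ids: np.ndarray  # n, int (globally unique per trial)
    segment_indices: np.ndarray  # n, position of segment within its trial
    test_masks: np.ndarray | None = None  # n_repeats x n bool, True = test

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def segments(self):
        for i in range(len(self)):
            yield Segment(
                self.data[i],
                int(self.labels[i]),
                str(self.subject_ids[i]),
                int(self.trial_ids[i]),
                int(self.segment_indices[i]),
            )

    def subset(self, idx) -> "SegmentDataset":
        return SegmentDataset(
            self.data[idx],
            self.labels[idx],
            self.subject_ids[idx],
            self.trial_ids[idx],
            self.segment_indices[idx],
        )

    @staticmethod
    def from_segments(segments: Sequence[Segment]) -> "SegmentDataset":
        if not segments:
            raise ValueError("empty segment list")
        return SegmentDataset(
            np.stack([s.data for s in segments]),
            np.array([s.label for s in segments], dtype=int),
            np.array([s.subject_id for s in segments]),
            np.array([s.trial_id for s in segments], dtype=int),
            np.array([s.segment_index for s in segments], dtype=int),
        )


def load_recording(path, expected_fs: float | None = None) -> RawRecording:
    """Load an EDF file, preserving channels and annotations.

    Subject and run ids are parsed from PhysioNet-style names (S001R04.edf)
    when present.
    """
    path = Path(path)
    signal, fs, names, ann = read_edf(path)
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise ValueError(
            f"{path.name}: sampling rate {fs} Hz does not match expected {expected_fs} Hz"
        )
    if not ann:
        raise ValueError(f"{path.name}: no events found in EDF annotations")
    m = re.match(r"S(\d+)R(\d+)", path.stem)
    subject = f"S{int(m.group(1)):03d}" if m else path.stem
    run = int(m.group(2)) if m else 0
    return RawRecording(signal, fs, names, ann, subject_id=subject, run_id=run)


def extract_trials(
    rec: RawRecording,
    run_task_map: Mapping[int, Mapping[str, str]] | Mapping[str, str] | None = None,
    trial_seconds: float = 4.0,
) -> list[TrialEvent]:
    """Turn non-rest annotations into fixed-length trial events.

    `run_task_map` maps annotation codes to task labels, either directly or
    nested per run id.  Trials running past the end of the record are
    dropped with a warning.
    """
    if run_task_map is None:
        run_task_map = PHYSIONET_RUN_TASK_MAP
    if run_task_map and all(isinstance(v, Mapping) for v in run_task_map.values()):
        try:
            code_map = run_task_map[rec.run_id]
        except KeyError:
            raise KeyError(f"run {rec.run_id} not present in run/task map") from None
    else:
        code_map = run_task_map

    n_trial = int(round(trial_seconds * rec.fs))
    trials: list[TrialEvent] = []
    for onset_s, _dur, code in rec.annotations:
        if code not in code_map:
            raise KeyError(
                f"annotation code {code!r} unknown; map covers {sorted(code_map)}"
            )
        task = code_map[code]
        if task in ("rest", "ignore"):
            continue
        if task not in LABEL_TO_INDEX:
            raise ValueError(f"mapped task {task!r} is not one of {LABELS}")
        onset = int(round(onset_s * rec.fs))
        if onset + n_trial > rec.n_samples:
            logger.warning(
                "dropping trial at %.2fs (%s): extends past end of record",
                onset_s,
                task,
            )
            continue
        trials.append(TrialEvent(task, onset, n_trial))
    return trials


def segment_trial(
    rec: RawRecording,
    trial: TrialEvent,
    segment_seconds: float = 0.4,
    stride_seconds: float | None = None,
    subject_id: str | None = None,
    trial_id: int = 0,
) -> list[Segment]:
    """Slice one trial into channels x timesteps windows (half-open intervals).

    Default stride equals the segment length (non-overlapping windows).
    """
    seg_len = int(round(segment_seconds * rec.fs))
    stride = seg_len if stride_seconds is None else int(round(stride_seconds * rec.fs))
    if seg_len > trial.n_samples:
        raise ValueError("segment longer than trial")
    if stride < 1:
        raise ValueError("stride must be at least one sample")
    label = LABEL_TO_INDEX[trial.label]
    subject = rec.subject_id if subject_id is None else subject_id
    out = []
    k = 0
    for start in range(0, trial.n_samples - seg_len + 1, stride):
        a = trial.onset_sample + start
        window = rec.signal[:, a : a + seg_len]
        if not np.all(np.isfinite(window)):
            raise ValueError("non-finite values in segment window")
        out.append(Segment(window.copy(), label, subject, trial_id, k))
        k += 1
    return out


def build_dataset(
    recordings: Sequence[RawRecording],
    run_task_map=None,
    trial_seconds: float = 4.0,
    segment_seconds: float = 0.4,
    stride_seconds: float | None = None,
) -> SegmentDataset:
    """Extract and segment trials from many recordings into one dataset."""
    segs: list[Segment] = []
    trial_counter = 0
    for rec in recordings:
        for trial in extract_trials(rec, run_task_map, trial_seconds):
            segs.extend(
                segment_trial(
                    rec,
                    trial,
                    segment_seconds,
                    stride_seconds,
                    trial_id=trial_counter,
                )
            )
            trial_counter += 1
    return SegmentDataset.from_segments(segs)


def make_splits(
    ds: SegmentDataset,
    test_fraction: float = 0.1,
    n_repeats: int = 10,
    seed: int = 0,
    trial_disjoint: bool = False,
) -> SegmentDataset:
    """Attach `n_repeats` independent random holdout partitions to `ds`.

    Each repeat draws round(test_fraction * n) test segments uniformly.
    With `trial_disjoint`, whole trials are assigned to one side so that no
    trial contributes segments to both train and test.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n = len(ds)
    if n == 0:
        raise ValueError("empty dataset")
    counts = np.bincount(ds.labels)
    if (counts < 1).any():
        missing = np.flatnonzero(counts < 1)
        raise ValueError(f"each class needs at least one segment; missing {missing}")
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_repeats, n), dtype=bool)
    if trial_disjoint:
        trials = np.unique(ds.trial_ids)
        n_test_trials = int(round(test_fraction * len(trials)))
        for r in range(n_repeats):
            test_trials = rng.choice(trials, size=n_test_trials, replace=False)
            masks[r] = np.isin(ds.trial_ids, test_trials)
    else:
        n_test = int(round(test_fraction * n))
        for r in range(n_repeats):
            idx = rng.choice(n, size=n_test, replace=False)
            masks[r, idx] = True
    ds.test_masks = masks
    return ds


def zscore_by_train(ds: SegmentDataset, repeat: int) -> SegmentDataset:
    """Optional per-channel z-scoring using training-partition statistics only."""
    if ds.test_masks is None:
        raise ValueError("splits not assigned")
    train = ~ds.test_masks[repeat]
    mu = ds.data[train].mean(axis=(0, 2), keepdims=True)
    sd = ds.data[train].std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    out = SegmentDataset(
        (ds.data - mu) / sd,
        ds.labels,
        ds.subject_ids,
        ds.trial_ids,
        ds.segment_indices,
        ds.test_masks,
    )
    return out
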