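"""HDF5 persistence for segment datasets and feature tables, plus CSV index."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import SegmentDataset
from .extractor import FeatureTable


def save_dataset(path, ds: SegmentDataset, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset(
            "subject_ids", data=np.asarray(ds.subject_ids, dtype="S16")
        )
        f.create_dataset("trial_ids", data=ds.trial_ids)
        f.create_dataset("segment_indices", data=ds.segment_indices)
        if ds.test_masks is not None:
            f.create_dataset("test_masks", data=ds.test_masks)
        f.attrs["config_hash"] = config_hash


def load_dataset(path) -> SegmentDataset:
    with h5py.File(path, "r") as f:
        masks = f["test_masks"][:] if "test_masks" in f else None
        return SegmentDataset(
            f["data"][:],
            f["labels"][:],
            f["subject_ids"][:].astype(str),
            f["trial_ids"][:],
            f["segment_indices"][:],
            masks,
        )


def dataset_index(ds: SegmentDataset) -> pd.DataFrame:
    """Tabular per-segment index (subject, trial, segment, label, folds)."""
    df = pd.DataFrame(
        {
            "subject": ds.subject_ids,
            "trial": ds.trial_ids,
            "segment": ds.segment_indices,
            "label": ds.labels,
        }
    )
    if ds.test_masks is not None:
        for r in range(ds.test_masks.shape[0]):
            df[f"test_fold_{r}"] = ds.test_masks[r]
    return df


def save_features(path, table: FeatureTable) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=table.features)
        f.create_dataset("labels", data=table.labels)
        if table.test_masks is not None:
            f.create_dataset("test_masks", data=table.test_masks)


def load_features(path) -> FeatureTable:
    with h5py.File(path, "r") as f:
        masks = f["test_masks"][:] if "test_masks" in f else None
        return FeatureTable(f["features"][:], f["labels"][:], masks)


def features_to_csv(path, table: FeatureTable) -> None:
    """n x (fc_size + 1) CSV: feature columns then the class label."""
    df = pd.DataFrame(
        table.features, columns=[f"f{i}" for i in range(table.features.shape[1])]
    )
    df["label"] = table.labels
    df.to_csv(path, index=False)
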