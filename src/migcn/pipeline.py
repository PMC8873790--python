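"""End-to-end pipeline: split → extractor → features → graph → GCN → report.

The repeated-holdout driver mirrors the published protocol: for each
repeat a fresh 90/10 segment-level split, extractor training on the train
partition, feature extraction for all segments, a Pearson feature graph
(train partition only by default, to avoid test leakage; `graph_data="all"`
reproduces the original estimate-from-overall-data variant), GCN training
and evaluation on the held-out segments.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .data import SegmentDataset, make_splits
from .extractor import ExtractorConfig, extract_features, train_extractor
from .gcn import GCNConfig, predict_proba, train_gcn
from .graph import build_feature_graph
from .metrics import EvalReport, evaluate_predictions, summary_stats

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the global seed
SEED_SPLIT, SEED_EXTRACTOR, SEED_GCN = 11, 23, 37


def desk_configs(seed: int = 0) -> tuple[ExtractorConfig, GCNConfig]:
    """Reduced single-CPU study configuration for the synthetic conditions.

    Cell size 32, attention 8, 16 FC features; two graph-convolution layers
    (8 and 16 filters, pool 2 each, K = 3 terms); practical Adam learning
    rates of 1e-3 and 15 epochs per stage — enough for the synthetic task
    to converge while keeping a full run to a couple of minutes.
    """
    e_cfg = ExtractorConfig(
        cell_size=32,
        attention_size=8,
        fc_size=16,
        learning_rate=1e-3,
        batch_size=256,
        epochs=15,
        seed=seed,
    )
    g_cfg = GCNConfig(
        filters_per_layer=[8, 16],
        pool_per_layer=[2, 2],
        K=3,
        learning_rate=1e-3,
        batch_size=64,
        epochs=15,
        seed=seed,
    )
    return e_cfg, g_cfg


def run_single(
    ds: SegmentDataset,
    extractor_cfg: ExtractorConfig,
    gcn_cfg: GCNConfig,
    repeat: int = 0,
    graph_data: str = "train",
) -> tuple[EvalReport, dict]:
    """Train and evaluate one split; returns (report, stage logs)."""
    if ds.test_masks is None:
        raise ValueError("dataset has no split assignments; call make_splits first")
    test = ds.test_masks[repeat]
    train_ds = ds.subset(~test)
    logger.info(
        "repeat %d: %d train / %d test segments", repeat, len(train_ds), int(test.sum())
    )
    model, ext_log = train_extractor(train_ds, extractor_cfg)
    table = extract_features(ds, model)
    if graph_data == "train":
        graph_rows = table.features[~test]
    elif graph_data == "all":
        logger.warning("building graph from train+test features (leakage caveat)")
        graph_rows = table.features
    else:
        raise ValueError("graph_data must be 'train' or 'all'")
    graph = build_feature_graph(graph_rows)
    gcn, gcn_log = train_gcn(
        (table.features[~test], table.labels[~test]), graph, gcn_cfg
    )
    probs = predict_proba(gcn, table.features[test])
    report = evaluate_predictions(
        table.labels[test], probs.argmax(axis=1), probs, extractor_cfg.n_classes
    )
    return report, {"extractor": ext_log, "gcn": gcn_log}


def run_crossval(
    ds: SegmentDataset,
    extractor_cfg: ExtractorConfig,
    gcn_cfg: GCNConfig,
    n_repeats: int = 10,
    seed: int = 0,
    test_fraction: float = 0.1,
    graph_data: str = "train",
):
    """Repeated random-holdout validation; returns (reports, summary)."""
    ds = make_splits(ds, test_fraction, n_repeats, seed + SEED_SPLIT)
    reports = []
    for r in range(n_repeats):
        e_cfg = replace(extractor_cfg, seed=seed + SEED_EXTRACTOR + r)
        g_cfg = replace(gcn_cfg, seed=seed + SEED_GCN + r)
        try:
            report, _ = run_single(ds, e_cfg, g_cfg, repeat=r, graph_data=graph_data)
        except Exception:
            logger.error("repeat %d failed (seed %d)", r, seed)
            raise
        reports.append(report)
    summary = {
        metric: summary_stats([getattr(rep, metric) for rep in reports])
        for metric in ("gaa", "kappa", "precision", "recall", "f1")
    }
    return reports, summary


def permute_labels(ds: SegmentDataset, seed: int = 0) -> SegmentDataset:
    """Chance-level control: shuffle labels across segments before training."""
    rng = np.random.default_rng(seed)
    out = SegmentDataset(
        ds.data,
        rng.permutation(ds.labels),
        ds.subject_ids,
        ds.trial_ids,
        ds.segment_indices,
        ds.test_masks,
    )
    return out
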