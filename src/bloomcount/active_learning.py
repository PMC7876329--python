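"""CountDiff-based sample prioritization and the data-quantity experiment.

For each unlabeled sample the integrated count T_c and the discrete peak
count T_d are computed from the model's predicted density map; the gap
``CountDiff = T_c - T_d`` flags samples whose peaks are poorly resolved,
and those are prioritized for oracle correction and retraining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting_peaks import PeakConfig, extract_peaks, integrate_count
from .density_targets import KernelConfig, gaussian_density_map
from .trainer import TrainingConfig, evaluate, train
from .unet_model import ModelSpec, UNet, predict_density

logger = logging.getLogger(__name__)

__all__ = ["SamplePriority", "RoundLedger", "rank_samples",
           "ingest_corrections", "incremental_experiment"]


@dataclass
class SamplePriority:
    sample_id: str
    t_c: float
    t_d: int
    count_diff: float

    def __post_init__(self):
        if self.t_d < 0:
            raise ValueError("t_d must be >= 0")
        if abs(self.count_diff - (self.t_c - self.t_d)) > 1e-9:
            raise ValueError("count_diff must equal t_c - t_d")


@dataclass
class RoundLedger:
    round_index: int
    training_size: int
    val_mse: float
    test_mae: float
    test_mse: float


def rank_samples(pool_predictions, config: PeakConfig | None = None):
    """Order samples by descending CountDiff (ties: ascending sample_id).

    ``pool_predictions`` is an iterable of ``(sample_id, density_map)``.
    The full per-sample priority record is returned for audit.
    """
    if config is None:
        config = PeakConfig()
    pool_predictions = list(pool_predictions)
    if not pool_predictions:
        raise ValueError("sample pool is empty")
    priorities = []
    for sample_id, density in pool_predictions:
        t_c = integrate_count(density)
        t_d = extract_peaks(density, config).count
        priorities.append(SamplePriority(sample_id, t_c, t_d, t_c - t_d))
    priorities.sort(key=lambda p: (-p.count_diff, p.sample_id))
    return priorities


def ingest_corrections(corrections: dict, kernel: KernelConfig,
                       manifest: pd.DataFrame, *, round_index: int = 0,
                       target_shapes: dict | None = None,
                       paths: dict | None = None) -> pd.DataFrame:
    """Append oracle-corrected samples to the training split.

    ``corrections`` maps sample_id -> PointAnnotationSet. Density targets
    are regenerated from the corrected points with the same kernel used
    for the original data (``target_shapes`` supplies (H, W) per sample
    when regeneration is requested); the validation and test splits are
    never touched, and a corrected id colliding with one of them is a
    split-contamination error. Provenance (round, source) is recorded on
    the appended rows.
    """
    held_out = set(manifest.loc[manifest["split"].isin(["val", "test"]),
                                "image_id"])
    clashes = sorted(set(corrections) & held_out)
    if clashes:
        raise ValueError(
            f"corrected samples {clashes} collide with validation/test "
            "split ids (split contamination)")
    out = manifest.copy()
    if "source" not in out.columns:
        out["source"] = "initial"
        out["round"] = 0
    rows = []
    for sample_id in sorted(corrections):
        ann = corrections[sample_id]
        row = {"image_id": sample_id, "split": "train", "path": "",
               "annotation_path": "", "source": "oracle",
               "round": round_index}
        if paths and sample_id in paths:
            row.update(paths[sample_id])
        if target_shapes and sample_id in target_shapes:
            target = gaussian_density_map(ann, target_shapes[sample_id],
                                          kernel)
            row["target_sum"] = target.sum()
        row["points"] = ann
        rows.append(row)
    return pd.concat([out, pd.DataFrame(rows)], ignore_index=True)


def incremental_experiment(full_training_pool, val_set, test_set, levels,
                           model_spec: ModelSpec, config: TrainingConfig,
                           peak_config: PeakConfig | None = None, *,
                           strategy: str = "countdiff",
                           keep_round_weights: bool = False):
    """Train at growing data levels, selecting additions by CountDiff.

    The first level is a seeded uniform draw from the pool; each later
    level adds the top-(level difference) pool samples ranked by CountDiff
    under the model trained at the previous level. Each round retrains
    from fresh initialization. ``strategy='random'`` gives the passive
    baseline. Test data never participates in selection.

    Returns ``(ledgers, selections, model)`` where ``selections[i]`` lists
    the sample ids added at round i; with ``keep_round_weights`` a fourth
    element holds each round's trained weights for audit.
    """
    if peak_config is None:
        peak_config = PeakConfig()
    levels = list(levels)
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError(f"levels {levels} must be strictly increasing")
    if levels[-1] > len(full_training_pool):
        raise ValueError(
            f"level {levels[-1]} exceeds pool size {len(full_training_pool)}")
    if strategy not in ("countdiff", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    pool = {s.image_id: s for s in full_training_pool}
    held_out = {s.image_id for s in val_set} | {s.image_id for s in test_set}
    leak = sorted(held_out & set(pool))
    if leak:
        raise ValueError(f"pool samples {leak} also appear in a held-out "
                         "split (leakage)")

    rng = np.random.default_rng(config.seed)
    ids = sorted(pool)
    selected = [str(i) for i in
                rng.choice(ids, size=levels[0], replace=False)]
    selections = [list(selected)]
    ledgers = []
    round_weights = []
    model = None
    for round_index, level in enumerate(levels):
        if round_index > 0:
            k = level - len(selected)
            remaining = [i for i in ids if i not in set(selected)]
            if strategy == "countdiff":
                preds = ((i, predict_density(model, pool[i].image))
                         for i in remaining)
                ranked = rank_samples(preds, peak_config)
                added = [p.sample_id for p in ranked[:k]]
            else:
                added = [str(i) for i in
                         rng.choice(remaining, size=k, replace=False)]
            selected = selected + added
            selections.append(added)
        model = UNet(model_spec, seed=config.seed + round_index)
        best, history = train(model, [pool[i] for i in selected], val_set,
                              config)
        if keep_round_weights:
            round_weights.append(best)
        val_mse = min(h["val_mse"] for h in history)
        metrics, _ = evaluate(model, test_set, sigma=config.sigma)
        ledgers.append(RoundLedger(round_index, len(selected), val_mse,
                                   metrics.mae, metrics.pixel_mse))
        logger.info("round %d size=%d val_mse=%.5g test_mae=%.3f",
                    round_index, len(selected), val_mse, metrics.mae)
    if keep_round_weights:
        return ledgers, selections, model, round_weights
    return ledgers, selections, model


def ledgers_to_frame(ledgers) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in ledgers])
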