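"""De novo motif discovery by training a many-unit model.

Train one model (100 units by default) on labeled sequences, render every
unit's filter as a PWM on the validation set, rank the PWMs by unit
importance, score each by best-hit scanning (AUPRC for classification,
Pearson correlation against the signal for regression), and select the best
on validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .model import ModelConfig, build_model, ExplaiNNModel
from .train import TrainConfig, train
from .interpret import visualize_filters, unit_importance
from .motifs import PWM, scan_scores


class DiscoveryError(RuntimeError):
    pass


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve, step-wise interpolation.

    Thresholds sweep the distinct score values in descending order; the area
    is the sum of precision x recall-increment at each threshold (no linear
    interpolation). Requires at least one positive and one negative label.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float).astype(int)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("AUPRC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # collapse ties: evaluate only at the last index of each distinct score
    last_of_group = np.flatnonzero(np.diff(s_sorted, append=np.nan) != 0)
    tp, fp = tp[last_of_group], fp[last_of_group]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def evaluate_pwm(pwm: PWM, dataset: LabeledDataset, task: int = 0) -> float:
    """Score a PWM by best-hit scanning on a labeled dataset.

    Binary labels: AUPRC of the best-hit scores. Regression labels: Pearson
    correlation between best-hit scores and the signal. Multiclass: AUPRC of
    last class versus the rest (enrichment in the final selection cycle).
    """
    x = dataset.encode()
    scores = scan_scores(pwm, x)
    if dataset.task_type == "regression":
        return float(np.corrcoef(scores, dataset.labels[:, task])[0, 1])
    if dataset.task_type == "multiclass":
        labels = dataset.labels.argmax(axis=1) == dataset.num_tasks - 1
        return auprc(scores, labels)
    return auprc(scores, dataset.labels[:, task])


@dataclass
class DiscoveryResult:
    """Importance-ranked PWMs with their validation performance.

    ``pwms`` is sorted by descending unit-importance median (ties by unit
    index); ``best_pwm`` indexes the entry with the highest validation
    metric.
    """

    pwms: list
    unit_indices: list
    importances: list
    val_metrics: list
    best_pwm: int
    n_empty_units: int
    model: ExplaiNNModel | None = None
    history: pd.DataFrame | None = None

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(len(self.pwms)),
            "unit": self.unit_indices,
            "importance": self.importances,
            "val_metric": self.val_metrics,
        })


def _ranking_task(dataset: LabeledDataset) -> int:
    """Which task's importance ranks PWMs.

    Single-task data uses that task; multiclass (cycle-as-class) uses the
    last cycle, the one most enriched for bound sequences.
    """
    if dataset.task_type == "multiclass":
        return dataset.num_tasks - 1
    return 0


def discover(train_set: LabeledDataset, val_set: LabeledDataset,
             num_units: int = 100, train_config: TrainConfig | None = None,
             filter_width: int = 19, keep_model: bool = False) -> DiscoveryResult:
    """Run the full de novo discovery pipeline.

    Trains one model, extracts one PWM per unit from the validation
    sequences (units with no qualifying windows are dropped and counted),
    ranks PWMs by importance, and evaluates each by best-hit scanning on
    validation.
    """
    train_config = train_config if train_config is not None else TrainConfig()
    L = len(train_set.sequences[0])
    config = ModelConfig(num_units=num_units, input_length=L,
                         num_tasks=train_set.num_tasks,
                         filter_width=filter_width)
    model = build_model(config, seed=train_config.seed)
    model, history = train(model, train_set, val_set, train_config)

    interp_set = (val_set.with_reverse_complements()
                  if train_config.rc_augment else val_set)
    x_val = interp_set.encode()
    preds, _ = model.forward(x_val, training=False)
    pfms, pwms = visualize_filters(model, x_val, preds, interp_set.labels,
                                   task_type=train_set.task_type)
    importance = unit_importance(model, x_val, preds, interp_set.labels,
                                 task_type=train_set.task_type)
    task = _ranking_task(train_set)

    entries = []
    for u, pwm in enumerate(pwms):
        if pwm is None or not importance.defined[u, task]:
            continue
        entries.append((u, pwm, importance.medians[u, task]))
    n_empty = num_units - len(entries)
    if not entries:
        raise DiscoveryError(
            "every unit produced an empty PFM; train longer or use more units"
        )
    entries.sort(key=lambda e: (-e[2], e[0]))

    val_metrics = [evaluate_pwm(pwm, val_set) for _, pwm, _ in entries]
    best = int(np.argmax(val_metrics))
    return DiscoveryResult(
        pwms=[e[1] for e in entries],
        unit_indices=[e[0] for e in entries],
        importances=[e[2] for e in entries],
        val_metrics=val_metrics,
        best_pwm=best,
        n_empty_units=n_empty,
        model=model if keep_model else None,
        history=history,
    )
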