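"""Model interpretation: filter visualization, unit importance, annotation.

The model's transparency rests on two facts exploited here:

- Each unit's filter can be rendered as a PFM by aligning the filter-width
  subsequences that activate the unit at >= 50% of its dataset-wide maximum
  in correctly predicted sequences.
- Because the final layer is linear, the product of a unit's output with its
  final-layer weight IS that unit's exact contribution to a task's
  prediction; the median of these products over qualifying sequences scores
  the unit's importance, and zeroing the unit changes the prediction by
  exactly minus that contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ExplaiNNModel
from .motifs import PFM, PWM, pfm_to_pwm, pwm_similarity
from .train import sigmoid

DEFAULT_ACTIVATION_FRACTION = 0.5


@dataclass
class ActivationTable:
    """Per (unit, sequence) maxima of the post-exponential filter response.

    ``values``/``positions`` are (N, U); ``unit_max`` is the dataset-wide
    per-unit maximum over the provided sequences. Argmax ties resolve to the
    lowest position.
    """

    values: np.ndarray
    positions: np.ndarray
    unit_max: np.ndarray


def collect_activations(model: ExplaiNNModel, sequences,
                        batch_size: int = 512) -> ActivationTable:
    """Scan sequences through every unit's filter in evaluation mode."""
    x = model._as_batch(sequences)
    vals, poss = [], []
    for start in range(0, x.shape[0], batch_size):
        act = model.conv_activations(x[start:start + batch_size])  # (n, P, U)
        poss.append(act.argmax(axis=1))
        vals.append(act.max(axis=1))
    values = np.vstack(vals)
    positions = np.vstack(poss)
    return ActivationTable(values=values, positions=positions,
                           unit_max=values.max(axis=0))


# --------------------------------------------------------------------------
# correctness predicates
# --------------------------------------------------------------------------

def correctness_matrix(predictions: np.ndarray, labels: np.ndarray,
                       task_type: str,
                       regression_pcc_threshold: float = 0.75) -> np.ndarray:
    """(N, T) boolean matrix of per-task prediction correctness.

    binary_multitask: post-sigmoid >= 0.5 equals the 0/1 label, per task.
    multiclass: predicted class equals the labeled class (same for all
    columns). regression with T > 1: per-sequence Pearson across tasks >=
    threshold; with T = 1: absolute residual at or below the median absolute
    residual (the better-predicted half).
    """
    p, y = np.asarray(predictions, float), np.asarray(labels, float)
    n, t = p.shape
    if task_type == "binary_multitask":
        return (sigmoid(p) >= 0.5) == (y >= 0.5)
    if task_type == "multiclass":
        ok = p.argmax(axis=1) == y.argmax(axis=1)
        return np.repeat(ok[:, None], t, axis=1)
    if task_type == "regression":
        if t == 1:
            resid = np.abs(p[:, 0] - y[:, 0])
            ok = resid <= np.median(resid)
            return ok[:, None]
        pc = _rowwise_pearson(p, y)
        return np.repeat((pc >= regression_pcc_threshold)[:, None], t, axis=1)
    raise ValueError(f"unknown task type {task_type!r}")


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (a * b).sum(axis=1) / denom
    return np.where(denom > 0, out, 0.0)


# --------------------------------------------------------------------------
# filter -> PFM
# --------------------------------------------------------------------------

def filter_to_pfm(model: ExplaiNNModel, unit: int, sequences, predictions,
                  labels, fraction: float = DEFAULT_ACTIVATION_FRACTION,
                  activations: ActivationTable | None = None,
                  task_type: str | None = None,
                  correct_mode: str = "any_task") -> PFM:
    """Build a PFM from the filter-width windows that drive one unit.

    A sequence contributes its argmax window when it is correctly predicted
    (on at least one task by default, or on every task with
    ``correct_mode="all_tasks"``) and its max activation reaches
    ``fraction`` of the unit's dataset-wide maximum. Zero qualifying
    windows yield an empty PFM (``is_empty``), marking the unit
    non-interpretable on this set.
    """
    x = model._as_batch(sequences)
    task_type = task_type or "binary_multitask"
    if activations is None:
        activations = collect_activations(model, x)
    correct = correctness_matrix(predictions, labels, task_type)
    seq_ok = correct.all(axis=1) if correct_mode == "all_tasks" else correct.any(axis=1)
    act_ok = activations.values[:, unit] >= fraction * activations.unit_max[unit]
    qualifying = np.flatnonzero(seq_ok & act_ok)

    W = model.config.filter_width
    counts = np.zeros((4, W))
    for i in qualifying:
        p = activations.positions[i, unit]
        counts += x[i, p:p + W, :].T  # one-hot window -> 4 x W
    return PFM(counts, n_sites=float(len(qualifying)), id=f"unit{unit}")


def visualize_filters(model: ExplaiNNModel, sequences, predictions, labels,
                      fraction: float = DEFAULT_ACTIVATION_FRACTION,
                      task_type: str | None = None,
                      pseudocount: float = 1.0):
    """PFM and PWM for every unit; empty units get ``None`` for the PWM."""
    x = model._as_batch(sequences)
    activations = collect_activations(model, x)
    pfms, pwms = [], []
    for u in range(model.config.num_units):
        pfm = filter_to_pfm(model, u, x, predictions, labels,
                            fraction=fraction, activations=activations,
                            task_type=task_type)
        pfms.append(pfm)
        pwms.append(None if pfm.is_empty else pfm_to_pwm(pfm, pseudocount))
    return pfms, pwms


# --------------------------------------------------------------------------
# importance and nullification
# --------------------------------------------------------------------------

def final_layer_weights(model: ExplaiNNModel):
    """The exact linear combination: (U x T weight matrix, T bias vector)."""
    return model.params["final_w"].copy(), model.params["final_b"].copy()


@dataclass
class ImportanceMatrix:
    """Per-(unit, task) medians of activation x weight products.

    ``medians`` is U x T with NaN where the qualifying set was empty (the
    ``defined`` mask distinguishes a true zero from "no evidence");
    ``n_qualifying`` reports qualifying-set sizes.
    """

    medians: np.ndarray
    n_qualifying: np.ndarray
    defined: np.ndarray
    per_sequence_products: dict = field(default_factory=dict)


def unit_importance(model: ExplaiNNModel, sequences, predictions=None,
                    labels=None, fraction: float = DEFAULT_ACTIVATION_FRACTION,
                    task_type: str = "binary_multitask",
                    keep_products: bool = False) -> ImportanceMatrix:
    """Median of unit_output x final_weight over qualifying sequences.

    For each unit u and task t, the product is taken over sequences that are
    correctly predicted on task t and whose filter activation reaches
    ``fraction`` of u's dataset-wide maximum.
    """
    x = model._as_batch(sequences)
    preds, unit_out = model.forward(x, training=False)
    if predictions is None:
        predictions = preds
    activations = collect_activations(model, x)
    correct = correctness_matrix(predictions, labels, task_type)
    U, T = model.config.num_units, model.config.num_tasks
    w = model.params["final_w"]
    medians = np.full((U, T), np.nan)
    n_q = np.zeros((U, T), dtype=int)
    products_store = {}
    for u in range(U):
        act_ok = activations.values[:, u] >= fraction * activations.unit_max[u]
        for t in range(T):
            mask = act_ok & correct[:, t]
            n_q[u, t] = int(mask.sum())
            if n_q[u, t]:
                products = unit_out[mask, u] * w[u, t]
                medians[u, t] = np.median(products)
                if keep_products:
                    products_store[(u, t)] = products
    return ImportanceMatrix(medians=medians, n_qualifying=n_q,
                            defined=n_q > 0,
                            per_sequence_products=products_store)


def nullify_unit(model: ExplaiNNModel, unit: int) -> ExplaiNNModel:
    """Return a copy in which one unit's contribution is forced to zero.

    Implemented by zeroing the unit's final-layer weights, which by linearity
    changes every prediction by exactly -unit_output x weight. The original
    model is unmodified.
    """
    if not 0 <= unit < model.config.num_units:
        raise IndexError(f"unit index {unit} out of range")
    out = model.copy()
    out.params["final_w"][unit, :] = 0.0
    return out


def nullification_impact(model: ExplaiNNModel, sequences) -> np.ndarray:
    """(U, T) mean prediction change from nullifying each unit in turn.

    By linearity this equals minus the mean of unit_output x weight per
    (unit, task); computed here by actually re-running the nullified models
    so it can serve as an independent oracle for the importance scores.
    """
    x = model._as_batch(sequences)
    base, _ = model.forward(x, training=False)
    U, T = model.config.num_units, model.config.num_tasks
    impact = np.zeros((U, T))
    for u in range(U):
        pred_null, _ = nullify_unit(model, u).forward(x, training=False)
        impact[u] = (pred_null - base).mean(axis=0)
    return impact


# --------------------------------------------------------------------------
# annotation against a motif database
# --------------------------------------------------------------------------

@dataclass
class UnitAnnotation:
    unit: int
    motif_ids: list
    scores: list
    qvalues: list | None = None
    label: str = ""


def annotate_units(pwms, motif_db, backend: str = "internal_similarity",
                   threshold: float | None = None,
                   min_overlap: int = 5) -> list[UnitAnnotation]:
    """Match unit PWMs to database motifs.

    ``internal_similarity`` keeps matches whose best probability-column
    Pearson correlation over all offsets and strands reaches ``threshold``
    (default 0.8). ``tomtom_external`` shells out to a Tomtom binary and
    keeps matches with q-value <= ``threshold`` (default 0.05); if the
    binary is absent an actionable error points at the internal backend.
    """
    if backend == "tomtom_external":
        return _annotate_tomtom(pwms, motif_db,
                                0.05 if threshold is None else threshold)
    if backend != "internal_similarity":
        raise ValueError(f"unknown annotation backend {backend!r}")
    threshold = 0.8 if threshold is None else threshold
    annotations = []
    for u, query in enumerate(pwms):
        if query is None:
            annotations.append(UnitAnnotation(unit=u, motif_ids=[], scores=[]))
            continue
        hits = []
        for target in motif_db:
            score, _, _ = pwm_similarity(query, target, min_overlap=min_overlap)
            if score >= threshold:
                hits.append((score, target.id))
        hits.sort(reverse=True)
        annotations.append(UnitAnnotation(
            unit=u,
            motif_ids=[mid for _, mid in hits],
            scores=[s for s, _ in hits],
            label=hits[0][1] if hits else "",
        ))
    return annotations


def _annotate_tomtom(pwms, motif_db, qvalue_threshold):
    import shutil

    if shutil.which("tomtom") is None:
        raise RuntimeError(
            "the tomtom binary is not on PATH; use "
            "backend='internal_similarity' for the built-in PWM comparison"
        )
    import subprocess
    import tempfile
    from pathlib import Path

    from .motifs import write_meme

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        query_path, db_path = tmp / "query.meme", tmp / "db.meme"
        write_meme(query_path, [p for p in pwms if p is not None])
        db_pwms = [pfm_to_pwm(m) if isinstance(m, PFM) else m for m in motif_db]
        write_meme(db_path, db_pwms)
        subprocess.run(
            ["tomtom", "-oc", str(tmp / "out"), str(query_path), str(db_path)],
            check=True, capture_output=True)
        table = (tmp / "out" / "tomtom.tsv").read_text()
    return parse_tomtom(table, pwms, qvalue_threshold)


def parse_tomtom(table_text: str, pwms, qvalue_threshold: float):
    """Parse a Tomtom TSV into annotations (q-value filtered)."""
    name_to_unit = {p.id: u for u, p in enumerate(pwms) if p is not None}
    hits: dict[int, list] = {}
    for line in table_text.splitlines():
        if not line or line.startswith(("#", "Query_ID")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            continue
        query, target, qval = fields[0], fields[1], float(fields[5])
        if query in name_to_unit and qval <= qvalue_threshold:
            hits.setdefault(name_to_unit[query], []).append((qval, target))
    annotations = []
    for u, p in enumerate(pwms):
        matched = sorted(hits.get(u, []))
        annotations.append(UnitAnnotation(
            unit=u,
            motif_ids=[t for _, t in matched],
            scores=[-q for q, _ in matched],
            qvalues=[q for q, _ in matched],
            label=matched[0][1] if matched else "",
        ))
    return annotations
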