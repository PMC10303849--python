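"""Motif cooperativity: distance-dependence of non-additive predictions.

The analysis fixes one motif instance at the center of random background
sequences, embeds a second motif (or a control k-mer) at a signed
edge-to-edge distance d, and measures the deviation from additivity of a
predictor f on each backbone:

    residual(d) = f(both) - f(A alone) - f(B alone at d) + f(backbone)

The residual fold change is 2**residual (exact for log-scale outputs). A
predictor that is additive in motif occurrences gives residual 0 (fold
change 1) at every distance; an elevated fold change at short distances is
the signature of learned cooperativity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import ALPHABET
from .motifs import PWM

DEFAULT_CONTROL_KMER = "GGGCT"
DEFAULT_N_BACKBONES = 256


def generate_backbones(n: int, length: int, gc: float = 0.5,
                       seed: int | np.random.Generator = 0) -> list:
    """i.i.d. background sequences with the given GC content.

    Per-position base probabilities are ((1-gc)/2, gc/2, gc/2, (1-gc)/2)
    for A, C, G, T.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draws = rng.choice(4, size=(n, length), p=probs)
    lut = np.array(list(ALPHABET))
    return ["".join(row) for row in lut[draws]]


def embed(sequence: str, motif_instance: str, start: int) -> str:
    """Replace the substring at ``start`` with the motif instance.

    Overlapping embeddings follow replacement semantics: a later call wins
    on the overlap.
    """
    if start < 0 or start + len(motif_instance) > len(sequence):
        raise ValueError(
            f"embedding of length {len(motif_instance)} at {start} exceeds "
            f"sequence length {len(sequence)}"
        )
    return sequence[:start] + motif_instance + sequence[start + len(motif_instance):]


def center_start(length: int, motif_len: int) -> int:
    """Start placing the motif midpoint at length/2 (left-shifted on odd
    parity)."""
    return (length - motif_len) // 2


@dataclass
class CoopProfile:
    """Residual fold change against inter-motif distance.

    ``distances`` are signed bp offsets between motif edges (negative =
    sliding motif left of the centered one). ``mean_log2_residual`` averages
    the per-backbone residual at each distance; ``fold_change`` is 2 to that
    mean. ``skipped`` lists distances dropped for overlap/bounds.
    """

    motif_a: str
    motif_b: str
    distances: np.ndarray
    mean_log2_residual: np.ndarray
    sd: np.ndarray
    n_backbones: int
    is_control: bool = False
    skipped: list = field(default_factory=list)
    residuals: np.ndarray | None = None  # (n_distances, n_backbones)

    @property
    def fold_change(self) -> np.ndarray:
        return 2.0 ** self.mean_log2_residual

    @property
    def se(self) -> np.ndarray:
        return self.sd / np.sqrt(self.n_backbones)

    def flatness(self) -> tuple[float, float]:
        """(max |deviation from own mean|, max allowed by 3x the SE).

        Flatness here means absence of distance dependence: deviations are
        measured about the profile's own mean level, since a constant offset
        reflects saturation non-additivity rather than a learned distance
        effect.
        """
        dev = np.abs(self.mean_log2_residual - self.mean_log2_residual.mean())
        return float(dev.max()), float(3.0 * self.se.max())

    def window_contrast(self, window: int = 10,
                        far_min: int = 25) -> tuple[float, float]:
        """Near-vs-far contrast of the profile with a paired SE.

        Returns ``(contrast, se)`` where contrast is the mean log2 residual
        over |d| <= window minus that over |d| > far_min, computed per
        backbone and averaged; the SE is over backbones, which accounts for
        the correlation induced by the shared backbone, A-alone, and
        baseline predictions. A predictor with no distance dependence gives
        a contrast within a few SE of zero; a learned proximity bonus b
        gives a contrast near b.
        """
        if self.residuals is None:
            raise ValueError("profile was built without per-backbone residuals")
        d = np.abs(self.distances)
        near, far = d <= window, d > far_min
        if not near.any() or not far.any():
            raise ValueError("distance grid does not cover both windows")
        per_backbone = (self.residuals[near].mean(axis=0)
                        - self.residuals[far].mean(axis=0))
        se = per_backbone.std(ddof=1) / np.sqrt(per_backbone.size)
        return float(per_backbone.mean()), float(se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance": self.distances,
            "fold_change": self.fold_change,
            "log2_residual": self.mean_log2_residual,
            "sd": self.sd,
            "n": self.n_backbones,
        })


def _instance(motif) -> str:
    """Consensus string of a PWM, or the string itself."""
    return motif.consensus() if isinstance(motif, PWM) else str(motif)


def _placements(L, len_a, len_b, distances):
    """Start positions of the sliding motif per distance; None = infeasible."""
    a_start = center_start(L, len_a)
    out = []
    for d in distances:
        if d >= 0:
            b_start = a_start + len_a + d
        else:
            b_start = a_start + d - len_b
        if b_start < 0 or b_start + len_b > L:
            out.append(None)
        elif b_start < a_start + len_a and b_start + len_b > a_start:
            out.append(None)  # overlap
        else:
            out.append(b_start)
    return out


def distance_dependence(predictor, motif_a, motif_b, distances=None,
                        n_backbones: int = DEFAULT_N_BACKBONES,
                        length: int | None = None, gc: float = 0.5,
                        task_index: int = 0,
                        control_kmer: str | None = DEFAULT_CONTROL_KMER,
                        seed: int = 0, backbones=None):
    """Measure non-additivity of ``predictor`` for a motif pair by distance.

    ``predictor`` maps a list of sequences to per-sequence outputs (a 1-D
    array, or 2-D with ``task_index`` selecting the column). Motifs may be
    PWMs (their consensus is embedded) or plain strings. Returns
    ``(profile, control_profile)``; the control repeats the analysis with
    ``control_kmer`` in place of the sliding motif (None skips it).
    Distances whose placement would overlap the centered motif or leave the
    sequence are skipped and reported on the profile.
    """
    inst_a, inst_b = _instance(motif_a), _instance(motif_b)
    if backbones is None:
        if length is None:
            raise ValueError("provide either backbones or length")
        backbones = generate_backbones(n_backbones, length, gc, seed)
    else:
        length = len(backbones[0])
        n_backbones = len(backbones)
    if distances is None:
        distances = np.arange(-(length // 2), length // 2 + 1)
    distances = np.asarray(list(distances), dtype=int)

    profile = _one_profile(predictor, backbones, inst_a, inst_b, distances,
                           task_index, is_control=False,
                           name_a=getattr(motif_a, "id", "") or inst_a,
                           name_b=getattr(motif_b, "id", "") or inst_b)
    control = None
    if control_kmer:
        control = _one_profile(predictor, backbones, inst_a, control_kmer,
                               distances, task_index, is_control=True,
                               name_a=getattr(motif_a, "id", "") or inst_a,
                               name_b=control_kmer)
    return profile, control


def homotypic_profile(predictor, motif, distances=None, **kwargs):
    """Distance dependence for two instances of the same motif."""
    return distance_dependence(predictor, motif, motif, distances, **kwargs)


def _predict(predictor, sequences, task_index):
    out = np.asarray(predictor(sequences), dtype=float)
    if out.ndim == 2:
        out = out[:, task_index]
    return out


def _one_profile(predictor, backbones, inst_a, inst_b, distances, task_index,
                 is_control, name_a, name_b) -> CoopProfile:
    L = len(backbones[0])
    a_start = center_start(L, len(inst_a))
    placements = _placements(L, len(inst_a), len(inst_b), distances)
    feasible = [d for d, p in zip(distances, placements) if p is not None]
    skipped = [int(d) for d, p in zip(distances, placements) if p is None]
    starts = [p for p in placements if p is not None]

    with_a = [embed(bb, inst_a, a_start) for bb in backbones]
    batch = list(backbones) + with_a
    for b_start in starts:
        batch.extend(embed(bb, inst_b, b_start) for bb in backbones)       # B alone
    for b_start in starts:
        batch.extend(embed(sa, inst_b, b_start) for sa in with_a)          # A and B

    preds = _predict(predictor, batch, task_index)
    n = len(backbones)
    k = len(starts)
    p_bb = preds[:n]
    p_a = preds[n:2 * n]
    p_b = preds[2 * n:2 * n + k * n].reshape(k, n)
    p_ab = preds[2 * n + k * n:].reshape(k, n)

    residual = p_ab - p_a[None, :] - p_b + p_bb[None, :]  # (k, n)
    return CoopProfile(
        motif_a=name_a, motif_b=name_b,
        distances=np.asarray(feasible, dtype=int),
        mean_log2_residual=residual.mean(axis=1),
        sd=residual.std(axis=1, ddof=1) if n > 1 else np.zeros(k),
        n_backbones=n,
        is_control=is_control,
        skipped=skipped,
        residuals=residual,
    )


def model_predictor(model, task_index: int = 0, batch_size: int = 512):
    """Adapt a trained model into a sequences -> outputs callable."""
    from .encoding import encode_batch

    def predict(sequences):
        x, _, log = encode_batch(sequences)
        if log.n_discarded:
            raise ValueError("predictor received N-containing sequences")
        outs = []
        for start in range(0, x.shape[0], batch_size):
            pred, _ = model.forward(x[start:start + batch_size], training=False)
            outs.append(pred[:, task_index])
        return np.concatenate(outs)

    return predict
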