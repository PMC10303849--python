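"""Initialize unit filters from motif-database profiles.

Profiles are resized to the filter width, de-duplicated by farthest point
sampling on a motif-similarity matrix, doubled with their reverse
complements, converted to filter weights by subtracting the 0.25 background
from each probability, and written into the model's filters -- optionally
frozen (their gradients are nullified during training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ExplaiNNModel
from .motifs import PFM, PWM, pfm_to_pwm, pwm_similarity, resize_profile


@dataclass
class ProfileSet:
    """An ordered collection of (id, PFM) with an optional similarity matrix."""

    profiles: list  # list of PFM
    similarity: np.ndarray | None = None
    unit_mapping: dict = field(default_factory=dict)

    @property
    def ids(self) -> list:
        return [p.id for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)


def profile_to_filter(pwm_probs: np.ndarray) -> np.ndarray:
    """Convert a 4 x W probability matrix to filter weights.

    Weights are probabilities minus the 0.25 uniform background, so every
    column sums to zero and uninformative columns map to all-zero weights.
    """
    probs = np.asarray(pwm_probs, dtype=float)
    if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("profile columns must sum to 1")
    return probs - 0.25


def similarity_matrix(profiles, min_overlap: int = 5) -> np.ndarray:
    """Pairwise best PWM similarity (symmetric, unit diagonal)."""
    pwms = [pfm_to_pwm(p) if isinstance(p, PFM) else p for p in profiles]
    n = len(pwms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s, _, _ = pwm_similarity(pwms[i], pwms[j], min_overlap=min_overlap)
            sim[i, j] = sim[j, i] = s
    return sim


def read_similarity_tsv(path, ids) -> np.ndarray:
    """Import an externally computed similarity table (query, target, score).

    Symmetrized by the maximum of the two directions; the diagonal is 1.
    Useful for plugging in similarities from an external motif-comparison
    tool.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["query", "target", "score"])
    index = {pid: i for i, pid in enumerate(ids)}
    sim = np.eye(len(ids))
    for _, row in df.iterrows():
        if row["query"] in index and row["target"] in index:
            i, j = index[row["query"]], index[row["target"]]
            val = float(row["score"])
            sim[i, j] = max(sim[i, j], val) if i != j else 1.0
            sim[j, i] = sim[i, j]
    return sim


def farthest_point_sample(similarity: np.ndarray, k: int, ids=None) -> list:
    """Greedy de-duplication: repeatedly pick the profile farthest from the
    already-selected set (distance = 1 - similarity).

    The first pick is the profile with the largest mean distance to all
    others (the most dissimilar); each later pick maximizes the minimum
    distance to the selected set. Ties break by id order. Returns the k
    selected ids (or indices when ids is None) in pick order.
    """
    sim = np.asarray(similarity, dtype=float)
    n = sim.shape[0]
    if k > n:
        raise ValueError(f"cannot sample {k} profiles from {n}")
    ids = list(range(n)) if ids is None else list(ids)
    dist = 1.0 - sim
    mean_dist = dist.mean(axis=1)
    # ties by id order: argmax over (-mean_dist, id) lexicographic
    first = min(range(n), key=lambda i: (-mean_dist[i], ids[i]))
    selected = [first]
    remaining = set(range(n)) - {first}
    min_dist = dist[first].copy()
    while len(selected) < k:
        pick = min(remaining, key=lambda i: (-min_dist[i], ids[i]))
        selected.append(pick)
        remaining.discard(pick)
        min_dist = np.minimum(min_dist, dist[pick])
    return [ids[i] for i in selected]


def add_reverse_complements(profiles) -> list:
    """Each profile plus its reverse complement (ids suffixed ``_rc``)."""
    out = []
    for p in profiles:
        out.append(p)
        out.append(p.reverse_complement())
    return out


def build_profile_set(profiles, k: int | None = None,
                      similarity: np.ndarray | None = None,
                      target_width: int = 19,
                      with_reverse_complements: bool = True,
                      resize_strategy: str = "max_ic") -> ProfileSet:
    """Resize -> (optional) farthest-point de-duplicate -> add RCs."""
    resized = [resize_profile(p, target_width, strategy=resize_strategy)
               for p in profiles]
    if k is not None:
        if similarity is None:
            similarity = similarity_matrix(resized)
        chosen = farthest_point_sample(similarity, k, ids=list(range(len(resized))))
        resized = [resized[i] for i in chosen]
        similarity = None
    if with_reverse_complements:
        resized = add_reverse_complements(resized)
    return ProfileSet(profiles=resized, similarity=similarity)


def init_filters(model: ExplaiNNModel, profile_set: ProfileSet,
                 freeze: bool = False) -> ExplaiNNModel:
    """Write profile-derived weights into a model's filters (on a copy).

    Requires exactly one profile per unit, all at the filter width. The
    unit -> profile mapping is recorded on the profile set so annotations
    are known a priori. With ``freeze=True`` the filters' gradients are
    nullified during training, keeping them bit-identical.
    """
    U, W = model.config.num_units, model.config.filter_width
    if len(profile_set) != U:
        raise ValueError(
            f"profile set has {len(profile_set)} profiles, model has {U} units"
        )
    out = model.copy()
    for u, pfm in enumerate(profile_set.profiles):
        if pfm.width != W:
            raise ValueError(
                f"profile {pfm.id!r} has width {pfm.width}, filters are {W}"
            )
        pwm = pfm_to_pwm(pfm) if not pfm.is_empty else None
        if pwm is None:
            raise ValueError(f"profile {pfm.id!r} is empty")
        out.params["filters"][u] = profile_to_filter(pwm.probs)
        profile_set.unit_mapping[u] = pfm.id
    out.frozen_filter_mask[:] = freeze
    return out


def mapping_report(profile_set: ProfileSet) -> pd.DataFrame:
    return pd.DataFrame(
        {"unit": list(profile_set.unit_mapping.keys()),
         "profile_id": list(profile_set.unit_mapping.values())}
    )
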