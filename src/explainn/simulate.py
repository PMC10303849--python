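"""Ground-truth synthetic datasets for benchmarking and testing.

Sequences are drawn from a GC-parameterized background; motif instances
(sampled from their PWMs, or planted as consensus) are embedded at
controlled frequencies and positions, and every planted instance is
recorded in a ledger (sequence id, motif id, start, strand, instance).
Labels follow one of four rules exactly:

- ``presence_binary``: 1 iff the sequence carries at least one instance
- ``linear_counts``: y = sum_k w_k * count_k + Gaussian noise
- ``homotypic_pairwise``: linear_counts plus a bonus when two instances of
  the pair motif co-occur within a distance window
- ``heterotypic_pairwise``: as above for instances of two different motifs

GC-matched negative sampling and dinucleotide shuffling (Altschul-Erickson
Eulerian walk) provide the two background-construction strategies used with
real peak sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .encoding import ALPHABET, reverse_complement
from .motifs import PWM

LABEL_RULES = ("presence_binary", "linear_counts",
               "homotypic_pairwise", "heterotypic_pairwise")


@dataclass
class PlantSpec:
    """What to generate: motifs, embedding plan, label rule, noise.

    ``embed_prob`` gives each motif's per-sequence embedding probability
    (for ``presence_binary`` it applies to the positive half only). For the
    pairwise rules, ``pair_motifs`` names the interacting pair and each
    sequence receives, with probability ``pair_prob``, a second qualifying
    instance at an edge-to-edge distance drawn uniformly from
    ``pair_distances``.
    """

    motifs: dict  # id -> PWM or consensus string
    n: int = 1000
    length: int = 100
    gc: float = 0.5
    seed: int = 0
    label_rule: str = "presence_binary"
    embed_prob: dict = field(default_factory=dict)  # id -> probability
    weights: dict = field(default_factory=dict)  # id -> linear weight
    bonus: float = 0.0
    window: int = 10
    noise_sd: float = 0.0
    pair_motifs: tuple | None = None
    pair_prob: float = 0.5
    pair_distances: tuple = tuple(range(1, 31))
    positions: str = "uniform"  # "uniform" | "center"
    sample_instances: bool = True
    both_strands: bool = False

    def validate(self):
        if self.label_rule not in LABEL_RULES:
            raise ValueError(f"unknown label rule {self.label_rule!r}")
        if not self.motifs:
            raise ValueError("at least one motif is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for mid, m in self.motifs.items():
            w = m.width if isinstance(m, PWM) else len(m)
            if w > self.length:
                raise ValueError(
                    f"motif {mid!r} (width {w}) does not fit in length "
                    f"{self.length}"
                )
        for p in self.embed_prob.values():
            if not 0 <= p <= 1:
                raise ValueError("embedding probabilities must be in [0, 1]")
        if self.label_rule.endswith("pairwise") and self.pair_motifs is None:
            raise ValueError("pairwise label rules require pair_motifs")


def _motif_width(m) -> int:
    return m.width if isinstance(m, PWM) else len(m)


def _draw_instance(m, rng, sample: bool) -> str:
    if not isinstance(m, PWM):
        return str(m)
    if not sample:
        return m.consensus()
    cols = [rng.choice(4, p=col / col.sum()) for col in m.probs.T]
    return "".join(ALPHABET[i] for i in cols)


def _free_start(rng, length, width, occupied, max_tries=100):
    """Uniform non-overlapping placement by rejection sampling."""
    for _ in range(max_tries):
        start = int(rng.integers(0, length - width + 1))
        if all(start + width <= s or start >= s + w for s, w in occupied):
            return start
    return None


def generate(spec: PlantSpec, seed: int | None = None):
    """Generate a labeled dataset plus a ground-truth ledger.

    Returns ``(LabeledDataset, ledger DataFrame, params)`` where the ledger
    has one row per planted instance and ``params`` echoes the label-rule
    parameters for parameter-recovery checks. Deterministic for a given
    seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    probs = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    lut = np.array(list(ALPHABET))
    motif_ids = list(spec.motifs)

    sequences, ids, ledger_rows = [], [], []
    for i in range(spec.n):
        sid = f"seq{i}"
        seq = "".join(lut[rng.choice(4, size=spec.length, p=probs)])
        occupied: list = []
        planted: list = []

        def plant(mid, start=None):
            nonlocal seq
            m = spec.motifs[mid]
            width = _motif_width(m)
            inst = _draw_instance(m, rng, spec.sample_instances)
            strand = "+"
            if spec.both_strands and rng.random() < 0.5:
                inst, strand = reverse_complement(inst), "-"
            if start is None:
                if spec.positions == "center":
                    start = (spec.length - width) // 2
                else:
                    start = _free_start(rng, spec.length, width, occupied)
                if start is None:
                    return False
            seq = seq[:start] + inst + seq[start + width:]
            occupied.append((start, width))
            planted.append((mid, start, width))
            ledger_rows.append({"sequence_id": sid, "motif_id": mid,
                                "start": start, "strand": strand,
                                "instance": inst})
            return True

        if spec.label_rule == "presence_binary":
            if i < (spec.n + 1) // 2:  # positive half
                for mid in motif_ids:
                    if rng.random() < spec.embed_prob.get(mid, 1.0):
                        plant(mid)
        elif spec.label_rule == "homotypic_pairwise":
            mid_a, _ = spec.pair_motifs
            r = rng.random()
            if r < spec.pair_prob:
                _plant_pair(spec, rng, plant, occupied, mid_a, mid_a)
            elif r < spec.pair_prob + (1 - spec.pair_prob) / 2:
                plant(mid_a)
        elif spec.label_rule == "heterotypic_pairwise":
            # pairs are drawn from {AA, BB, AB} with equal probability but
            # only the heterotypic pair earns the bonus: proximity of two
            # instances alone must not predict the label, otherwise a single
            # dual-specificity filter could shortcut the heterotypic logic
            mid_a, mid_b = spec.pair_motifs
            r = rng.random()
            if r < spec.pair_prob:
                kind = rng.integers(3)
                first, second = ((mid_a, mid_a), (mid_b, mid_b),
                                 (mid_a, mid_b))[kind]
                _plant_pair(spec, rng, plant, occupied, first, second)
            elif r < spec.pair_prob + (1 - spec.pair_prob) / 2:
                plant(mid_a if rng.random() < 0.5 else mid_b)
            # remaining sequences stay background
            for mid in motif_ids:
                if mid not in (mid_a, mid_b) and rng.random() < spec.embed_prob.get(mid, 0.0):
                    plant(mid)
        else:  # linear_counts
            for mid in motif_ids:
                p = spec.embed_prob.get(mid, 0.5)
                if rng.random() < p:
                    plant(mid)

        sequences.append(seq)
        ids.append(sid)

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["sequence_id", "motif_id", "start", "strand", "instance"])
    labels = labels_from_ledger(spec, ids, ledger)
    if spec.noise_sd > 0:
        labels = labels + rng.normal(0.0, spec.noise_sd, size=labels.shape)
    task_type = ("binary_multitask" if spec.label_rule == "presence_binary"
                 else "regression")
    dataset = LabeledDataset(ids=ids, sequences=sequences, labels=labels,
                             task_type=task_type, task_names=["y"])
    params = {"rule": spec.label_rule, "weights": dict(spec.weights),
              "bonus": spec.bonus, "window": spec.window,
              "noise_sd": spec.noise_sd}
    return dataset, ledger, params


def _plant_pair(spec, rng, plant, occupied, mid_a, mid_b):
    """Place a qualifying pair at a controlled edge-to-edge distance."""
    wa = _motif_width(spec.motifs[mid_a])
    wb = _motif_width(spec.motifs[mid_b])
    d = int(rng.choice(spec.pair_distances))
    span = wa + d + wb
    if span > spec.length:
        raise ValueError(
            f"pair at distance {d} (span {span}) exceeds length {spec.length}"
        )
    start_a = int(rng.integers(0, spec.length - span + 1))
    plant(mid_a, start=start_a)
    plant(mid_b, start=start_a + wa + d)


def labels_from_ledger(spec: PlantSpec, ids, ledger: pd.DataFrame) -> np.ndarray:
    """Recompute labels exactly from the planted-instance ledger."""
    by_seq = ledger.groupby("sequence_id") if len(ledger) else None
    labels = np.zeros((len(ids), 1))
    for i, sid in enumerate(ids):
        rows = (by_seq.get_group(sid)
                if by_seq is not None and sid in by_seq.groups else None)
        if spec.label_rule == "presence_binary":
            labels[i, 0] = 0.0 if rows is None else 1.0
            continue
        y = 0.0
        if rows is not None:
            counts = rows["motif_id"].value_counts()
            for mid, c in counts.items():
                y += spec.weights.get(mid, 0.0) * c
            if spec.label_rule.endswith("pairwise"):
                y += spec.bonus * _has_close_pair(spec, rows)
        labels[i, 0] = y
    return labels


def _has_close_pair(spec: PlantSpec, rows: pd.DataFrame) -> float:
    mid_a, mid_b = spec.pair_motifs
    a_rows = rows[rows["motif_id"] == mid_a]
    b_rows = rows[rows["motif_id"] == mid_b]
    wa = _motif_width(spec.motifs[mid_a])
    wb = _motif_width(spec.motifs[mid_b])
    pairs = []
    if spec.label_rule == "homotypic_pairwise":
        starts = sorted(a_rows["start"])
        pairs = [(s1, wa, s2, wa) for i, s1 in enumerate(starts)
                 for s2 in starts[i + 1:]]
    else:
        pairs = [(sa, wa, sb, wb) for sa in a_rows["start"]
                 for sb in b_rows["start"]]
    for s1, w1, s2, w2 in pairs:
        if s1 <= s2:
            gap = s2 - (s1 + w1)
        else:
            gap = s1 - (s2 + w2)
        if gap <= spec.window:
            return 1.0
    return 0.0


# --------------------------------------------------------------------------
# negatives
# --------------------------------------------------------------------------

def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)


def gc_matched_negatives(positives, pool, ratio: float = 1.0,
                         bin_width: float = 0.05, seed: int = 0):
    """Sample negatives from a pool matching the positives' GC histogram.

    Per bin of ``bin_width`` GC fraction, draw (positive count x ratio,
    rounded) pool sequences without replacement; shortfalls borrow from the
    nearest adjacent bins and are logged. Returns ``(negatives,
    report DataFrame)``; raises with a per-bin deficit report if the pool
    is exhausted even with borrowing.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(1.0 / bin_width))
    bin_of = lambda s: min(int(gc_fraction(s) / bin_width), n_bins - 1)

    pos_counts = np.zeros(n_bins, dtype=int)
    for s in positives:
        pos_counts[bin_of(s)] += 1
    wanted = np.round(pos_counts * ratio).astype(int)

    pool_bins: dict[int, list] = {b: [] for b in range(n_bins)}
    for i, s in enumerate(pool):
        pool_bins[bin_of(s)].append(i)
    for b in pool_bins:
        rng.shuffle(pool_bins[b])

    taken, report_rows = [], []
    deficits = {}
    for b in range(n_bins):
        need = wanted[b]
        got = pool_bins[b][:need]
        pool_bins[b] = pool_bins[b][need:]
        borrowed = 0
        offset = 1
        while len(got) < need and offset < n_bins:
            for nb in (b - offset, b + offset):
                if 0 <= nb < n_bins and len(got) < need:
                    take = min(need - len(got), len(pool_bins[nb]))
                    got.extend(pool_bins[nb][:take])
                    pool_bins[nb] = pool_bins[nb][take:]
                    borrowed += take
            offset += 1
        if len(got) < need:
            deficits[b] = need - len(got)
        taken.extend(got)
        report_rows.append({"bin": b, "gc_lo": b * bin_width,
                            "wanted": int(need), "sampled": len(got),
                            "borrowed": borrowed})
    report = pd.DataFrame(report_rows)
    if deficits:
        detail = ", ".join(f"bin {b}: short {d}" for b, d in deficits.items())
        raise ValueError(f"negative pool exhausted even with borrowing ({detail})")
    return [pool[i] for i in taken], report


# --------------------------------------------------------------------------
# dinucleotide shuffling
# --------------------------------------------------------------------------

def dinucleotide_counts(seq: str) -> dict:
    counts: dict = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator = 0) -> str:
    """Shuffle preserving the exact dinucleotide count multiset.

    Altschul-Erickson construction: treat characters as vertices and
    dinucleotides as directed edges, draw a random spanning arborescence
    into the final character (rejection sampling on the chosen last edges),
    shuffle the remaining out-edges, and walk the Eulerian path from the
    first character. Same length and same first character as the input.
    """
    seq = str(sequence)
    if len(seq) < 2:
        raise ValueError("dinucleotide shuffling needs length >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges: dict[str, list] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)

    # choose one terminal edge per non-final vertex such that every vertex
    # reaches the final character through the chosen edges
    while True:
        chosen = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            chosen[v] = edges[v][int(rng.integers(len(edges[v])))]
        for v in vertices:
            if v == last:
                continue
            seen, cur = {v}, v
            while cur != last:
                cur = chosen.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list] = {}
    for v, out in edges.items():
        out = list(out)
        if v in chosen:
            out.remove(chosen[v])
        rng.shuffle(out)
        if v in chosen:
            out.append(chosen[v])
        shuffled[v] = out

    result = [seq[0]]
    cur = seq[0]
    pos = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)
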