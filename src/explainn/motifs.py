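"""Position frequency/weight matrices and their file formats.

Matrices are 4 x W with rows in A, C, G, T order. A PFM holds counts whose
columns each sum to the number of contributing sites; a PWM holds column-
normalized probabilities and log2 odds against a uniform 0.25 background.

JASPAR (bracketed and 4-line dialects) and MEME-minimal files are read via
Bio.motifs; JASPAR writing goes through Bio.motifs as well, while the
MEME-minimal writer is local (Biopython has none).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .encoding import one_hot_encode

BASES = "ACGT"
BACKGROUND = 0.25


@dataclass
class PFM:
    """A 4 x W count matrix (rows A, C, G, T) from n_sites aligned sites."""

    counts: np.ndarray
    n_sites: float
    id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_sites == 0

    def probabilities(self) -> np.ndarray:
        """Column-normalized counts without pseudocounts."""
        if self.is_empty:
            raise ValueError(f"PFM {self.id!r} has no sites")
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def reverse_complement(self) -> "PFM":
        return PFM(self.counts[::-1, ::-1].copy(), self.n_sites,
                   id=f"{self.id}_rc" if self.id else "rc")


@dataclass
class PWM:
    """Column-stochastic probabilities plus log2 odds vs 0.25 background."""

    probs: np.ndarray
    id: str = ""
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.id!r} columns must sum to 1")
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.probs / BACKGROUND)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        """Argmax base per column (ties resolve to A < C < G < T order)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(),
                   id=f"{self.id}_rc" if self.id else "rc")


def pfm_to_pwm(pfm: PFM, pseudocount: float = 1.0) -> PWM:
    """Convert counts to probabilities with a uniformly distributed
    pseudocount, then to log2 odds against the 0.25 background.

    Per column: p = (counts + pseudocount/4) / (n_sites + pseudocount).
    A uniform column yields all-zero log odds.
    """
    if pfm.is_empty:
        raise ValueError(f"cannot convert empty PFM {pfm.id!r}")
    probs = (pfm.counts + pseudocount / 4.0) / (pfm.n_sites + pseudocount)
    return PWM(probs, id=pfm.id)


# --------------------------------------------------------------------------
# similarity and scanning
# --------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def pwm_similarity(query: PWM, target: PWM, min_overlap: int = 5):
    """Best Pearson correlation of probability columns over all offsets and
    both strands.

    Returns ``(score, offset, strand)`` where ``offset`` is the position of
    the target's first column relative to the query's first column and
    ``strand`` is ``+`` or ``-``. Overlaps shorter than ``min_overlap``
    columns are not considered.
    """
    best = (-np.inf, 0, "+")
    for strand, tgt in (("+", target), ("-", target.reverse_complement())):
        wq, wt = query.width, tgt.width
        for offset in range(-(wt - min_overlap), wq - min_overlap + 1):
            q_lo, q_hi = max(0, offset), min(wq, offset + wt)
            if q_hi - q_lo < min_overlap:
                continue
            t_lo = q_lo - offset
            q_cols = query.probs[:, q_lo:q_hi]
            t_cols = tgt.probs[:, t_lo:t_lo + (q_hi - q_lo)]
            score = _pearson(q_cols, t_cols)
            if score > best[0]:
                best = (score, offset, strand)
    return best


def scan_best_hit(pwm: PWM, sequence) -> float:
    """Best log-odds sum over all windows on both strands of a sequence.

    ``sequence`` is a DNA string or an (L, 4) one-hot matrix. Deterministic;
    a sequence shorter than the PWM width raises.
    """
    if isinstance(sequence, str):
        x = one_hot_encode(sequence, "scan").matrix
    else:
        x = np.asarray(sequence, dtype=float)
    if x.shape[0] < pwm.width:
        raise ValueError(
            f"sequence length {x.shape[0]} < PWM width {pwm.width}"
        )
    return float(scan_scores(pwm, x[None]).max())


def scan_scores(pwm: PWM, batch: np.ndarray) -> np.ndarray:
    """Per-sequence best-hit scores for an (N, L, 4) batch (both strands)."""
    W = pwm.width
    win = np.lib.stride_tricks.sliding_window_view(batch, W, axis=1)
    # win: (N, P, 4, W); log_odds: (4, W)
    fwd = np.einsum("npaw,aw->np", win, pwm.log_odds)
    rev = np.einsum("npaw,aw->np", win, pwm.reverse_complement().log_odds)
    return np.maximum(fwd.max(axis=1), rev.max(axis=1))


# --------------------------------------------------------------------------
# profile resizing (for filter initialization)
# --------------------------------------------------------------------------

def _column_ic(probs: np.ndarray) -> np.ndarray:
    """Per-column information content (bits) of a 4 x W probability matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs / BACKGROUND), 0.0)
    return terms.sum(axis=0)


def resize_profile(pfm: PFM, target_width: int = 19,
                   strategy: str = "max_ic") -> PFM:
    """Bring a PFM to a fixed width.

    Wider profiles are trimmed to the window of ``target_width`` columns with
    the highest total information content (``strategy="max_ic"``, ties to the
    leftmost window) or to the centered window (``strategy="center"``).
    Narrower profiles are padded on both sides with uniform columns (equal
    counts per base), the extra column going to the right on odd parity.
    """
    w = pfm.width
    if w == target_width:
        return PFM(pfm.counts.copy(), pfm.n_sites, id=pfm.id)
    if w > target_width:
        if strategy == "max_ic":
            ic = _column_ic(pfm.probabilities())
            window_ic = np.convolve(ic, np.ones(target_width), mode="valid")
            start = int(window_ic.argmax())
        elif strategy == "center":
            start = (w - target_width) // 2
        else:
            raise ValueError(f"unknown resize strategy {strategy!r}")
        counts = pfm.counts[:, start:start + target_width].copy()
        return PFM(counts, pfm.n_sites, id=pfm.id)
    pad = target_width - w
    left, right = pad // 2, pad - pad // 2
    uniform = np.full((4, 1), pfm.n_sites / 4.0)
    counts = np.hstack([np.tile(uniform, (1, left)), pfm.counts,
                        np.tile(uniform, (1, right))])
    return PFM(counts, pfm.n_sites, id=pfm.id)


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def _from_bio_motif(m) -> PFM:
    counts = np.array([m.counts[b] for b in BASES], dtype=float)
    n_sites = float(counts.sum(axis=0).max())
    return PFM(counts, n_sites, id=m.name or getattr(m, "matrix_id", "") or "")


def read_jaspar(path) -> list[PFM]:
    """Read JASPAR profiles (bracketed dialect, or the 4-line raw dialect)."""
    with open(path) as fh:
        text = fh.read()
    fmt = "jaspar" if ">" in text else "pfm"
    with io.StringIO(text) as handle:
        parsed = bio_motifs.parse(handle, fmt)
        return [_from_bio_motif(m) for m in parsed]


def write_jaspar(path, pfms) -> None:
    records = []
    for pfm in pfms:
        m = bio_motifs.Motif(
            counts={b: list(pfm.counts[i]) for i, b in enumerate(BASES)})
        m.name = pfm.id
        m.matrix_id = pfm.id
        records.append(m)
    with open(path, "w") as fh:
        fh.write(bio_motifs.write(records, "jaspar"))


def read_meme(path) -> list[PWM]:
    """Read a MEME minimal motif file into PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        probs = np.array([list(m.pwm[b]) for b in BASES], dtype=float)
        out.append(PWM(probs, id=m.name))
    return out


def write_meme(path, pwms, background: float = BACKGROUND) -> None:
    """Write PWMs in MEME minimal motif format (version 4)."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
             "Background letter frequencies",
             f"A {background:.5f} C {background:.5f} "
             f"G {background:.5f} T {background:.5f}", ""]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.id or 'motif'}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 20 E= 0"
        )
        for col in pwm.probs.T:
            lines.append(" ".join(f"{p:.6f}" for p in col))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
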