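"""Labeled sequence datasets, splitting, and file readers/writers.

A :class:`LabeledDataset` pairs equal-length DNA sequences with per-sequence
label vectors for one of three task types:

- ``binary_multitask``: T independent 0/1 labels (e.g. bound/unbound per TF)
- ``multiclass``: one-hot over classes (e.g. selection cycle of origin)
- ``regression``: real-valued vectors (e.g. accessibility or intensity)

Splitting supports random fractions (optionally stratified) and hold-out by
chromosome when region metadata is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import encode_batch, reverse_complement, DiscardLog

TASK_TYPES = ("binary_multitask", "multiclass", "regression")


class SplitError(ValueError):
    """A requested split cannot be realized on this dataset."""


@dataclass
class LabeledDataset:
    """Sequences with label vectors; the in-memory training currency."""

    ids: list
    sequences: list
    labels: np.ndarray  # (N, T)
    task_type: str = "binary_multitask"
    task_names: list | None = None
    chroms: list | None = None  # per-record chromosome, for by-chromosome splits

    def __post_init__(self):
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=float))
        if self.labels.shape[0] != len(self.ids):
            self.labels = self.labels.T
        if self.labels.shape[0] != len(self.ids):
            raise ValueError("labels and ids disagree in length")
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if self.task_names is None:
            self.task_names = [f"task{i}" for i in range(self.labels.shape[1])]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def num_tasks(self) -> int:
        return self.labels.shape[1]

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            ids=[self.ids[i] for i in indices],
            sequences=[self.sequences[i] for i in indices],
            labels=self.labels[indices],
            task_type=self.task_type,
            task_names=list(self.task_names),
            chroms=None if self.chroms is None else [self.chroms[i] for i in indices],
        )

    def drop_n_sequences(self) -> tuple["LabeledDataset", DiscardLog]:
        """Discard N-containing records, returning the survivors and a log."""
        log = DiscardLog()
        keep = []
        for i, s in enumerate(self.sequences):
            if "N" in s.upper():
                log.record(self.ids[i])
            else:
                keep.append(i)
        return self.subset(keep), log

    def with_reverse_complements(self) -> "LabeledDataset":
        """Each record plus its reverse complement with identical labels."""
        rc_ids = [f"{i}_rc" for i in self.ids]
        rc_seqs = [reverse_complement(s) for s in self.sequences]
        return LabeledDataset(
            ids=list(self.ids) + rc_ids,
            sequences=list(self.sequences) + rc_seqs,
            labels=np.vstack([self.labels, self.labels]),
            task_type=self.task_type,
            task_names=list(self.task_names),
            chroms=None if self.chroms is None else list(self.chroms) * 2,
        )

    def encode(self) -> np.ndarray:
        """One-hot encode all sequences into (N, L, 4); callers must have
        discarded N-containing records first."""
        x, kept, log = encode_batch(self.sequences, self.ids)
        if log.n_discarded:
            raise ValueError(
                f"{log.n_discarded} sequences contain N; call "
                "drop_n_sequences() before encoding"
            )
        return x


@dataclass
class SplitSpec:
    """How to partition a dataset into train/validation/test."""

    mode: str = "random_fractions"  # or "by_chromosome"
    fractions: tuple = (0.8, 0.1, 0.1)
    stratify: bool = False
    val_chroms: list = field(default_factory=list)
    test_chroms: list = field(default_factory=list)

    def validate(self):
        if self.mode not in ("random_fractions", "by_chromosome"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "random_fractions":
            if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
                raise ValueError("fractions must be three positive numbers")
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")
        if set(self.val_chroms) & set(self.test_chroms):
            raise ValueError("val_chroms and test_chroms overlap")


def _fraction_sizes(n: int, fractions) -> tuple[int, int, int]:
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split_dataset(dataset: LabeledDataset, spec: SplitSpec, seed: int = 0):
    """Partition into (train, val, test); every record lands in exactly one.

    Stratified random splits preserve the class ratio per split to within
    one record per class. Chromosome splits assign records exactly by
    membership in ``val_chroms`` / ``test_chroms``.
    """
    spec.validate()
    if len(dataset) == 0:
        raise SplitError("dataset is empty")
    if spec.mode == "by_chromosome":
        if dataset.chroms is None:
            raise SplitError("by_chromosome split requires region metadata")
        chroms = np.asarray(dataset.chroms)
        val_idx = np.flatnonzero(np.isin(chroms, spec.val_chroms))
        test_idx = np.flatnonzero(np.isin(chroms, spec.test_chroms))
        train_idx = np.flatnonzero(
            ~np.isin(chroms, list(spec.val_chroms) + list(spec.test_chroms)))
    else:
        rng = np.random.default_rng(seed)
        if spec.stratify:
            key = _strat_key(dataset)
            train_parts, val_parts, test_parts = [], [], []
            for cls in np.unique(key):
                idx = np.flatnonzero(key == cls)
                rng.shuffle(idx)
                n_tr, n_va, n_te = _fraction_sizes(len(idx), spec.fractions)
                train_parts.append(idx[:n_tr])
                val_parts.append(idx[n_tr:n_tr + n_va])
                test_parts.append(idx[n_tr + n_va:])
            train_idx = np.concatenate(train_parts)
            val_idx = np.concatenate(val_parts)
            test_idx = np.concatenate(test_parts)
        else:
            idx = rng.permutation(len(dataset))
            n_tr, n_va, n_te = _fraction_sizes(len(idx), spec.fractions)
            train_idx, val_idx, test_idx = (
                idx[:n_tr], idx[n_tr:n_tr + n_va], idx[n_tr + n_va:])
    parts = tuple(dataset.subset(np.sort(i)) for i in (train_idx, val_idx, test_idx))
    for name, part in zip(("train", "val", "test"), parts):
        if len(part) == 0:
            raise SplitError(
                f"{name} split is empty; provide a larger dataset or adjust "
                "the split specification"
            )
    return parts


def _strat_key(dataset: LabeledDataset) -> np.ndarray:
    """Per-record class key used for stratification."""
    if dataset.task_type == "multiclass":
        return dataset.labels.argmax(axis=1)
    if dataset.task_type == "binary_multitask":
        if dataset.num_tasks == 1:
            return dataset.labels[:, 0].astype(int)
        # multi-task: stratify on the joint label pattern
        return np.array([hash(tuple(row)) for row in dataset.labels.astype(int)])
    raise SplitError("stratified splitting requires a classification dataset")


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def read_fasta(path) -> tuple[list, list]:
    """Read a (possibly line-wrapped) FASTA file; ids are the header up to
    the first whitespace. Duplicate ids are rejected."""
    ids, seqs = [], []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ids, seqs


def write_fasta(path, ids, sequences, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(ids, sequences)]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_label_table(path) -> pd.DataFrame:
    """TSV with header ``id<TAB>task1..taskT``; duplicate ids rejected."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "id":
        raise ValueError(f"label table {path} must start with an 'id' column")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in label table {path}")
    return df.set_index("id")


def write_label_table(path, ids, labels, task_names) -> None:
    df = pd.DataFrame(np.atleast_2d(labels), columns=task_names)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_bed6(path) -> pd.DataFrame:
    """BED6 (0-based, half-open). Returns chrom/start/end/name/score/strand."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = cols[: df.shape[1]]
    for c, default in (("name", "."), ("score", 0), ("strand", "+")):
        if c not in df.columns:
            df[c] = default
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"{path} line {bad[0] + 1}: end <= start")
    return df


def extract_bed_sequences(bed: pd.DataFrame, genome_fasta) -> tuple[list, list]:
    """Extract BED interval sequences from a genome FASTA, honoring strand.

    Minus-strand intervals yield the reverse complement of the plus-strand
    extraction. Coordinates are 0-based half-open.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    ids, seqs = [], []
    for i, row in bed.iterrows():
        seq = str(genome[row["chrom"]][int(row["start"]):int(row["end"])]).upper()
        if row.get("strand", "+") == "-":
            seq = reverse_complement(seq)
        name = row.get("name", ".")
        ids.append(name if name not in (".", "") else
                   f"{row['chrom']}:{row['start']}-{row['end']}")
        seqs.append(seq)
    return ids, seqs


def dataset_from_files(fasta_path, labels_path, task_type="binary_multitask") -> LabeledDataset:
    ids, seqs = read_fasta(fasta_path)
    table = read_label_table(labels_path)
    missing = [i for i in ids if i not in table.index]
    if missing:
        raise ValueError(f"no labels for sequence id {missing[0]!r}")
    labels = table.loc[ids].to_numpy(dtype=float)
    return LabeledDataset(ids=ids, sequences=seqs, labels=labels,
                          task_type=task_type,
                          task_names=list(table.columns))
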