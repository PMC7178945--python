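"""FASTA input/output, sequence sanitation, and labeled dataset handling.

All downstream descriptors are defined over the 20 natural amino acids, so
:func:`sanitize` removes everything else (ambiguity codes, gaps, stops)
rather than remapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO as _BioSeqIO

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""Canonical alphabetical ordering of the 20 natural amino acids."""

_AA_SET = frozenset(AMINO_ACIDS)

LABEL_TRANSPORTER = "T"
LABEL_NON_TRANSPORTER = "NT"
VALID_LABELS = frozenset({LABEL_TRANSPORTER, LABEL_NON_TRANSPORTER})


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence restricted to the 20-letter amino acid alphabet.

    Instances are expected to be produced via :func:`sanitize` (or from
    already-clean residue strings); the constructor validates the alphabet.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-standard residues "
                f"{sorted(bad)}; run sanitize() first"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def sanitize(raw: str, seq_id: str = "<anonymous>") -> ProteinSequence:
    """Uppercase ``raw`` and delete residues outside the 20-letter alphabet.

    Gap characters (``-``, ``.``), stops (``*``) and ambiguity/nonstandard
    codes (B, J, O, U, X, Z) are removed; the reported length is the length
    of the filtered string.

    Raises
    ------
    SequenceError
        If nothing remains after filtering.
    """
    if not raw:
        raise SequenceError(f"sequence {seq_id!r}: empty input")
    filtered = "".join(c for c in raw.upper() if c in _AA_SET)
    if not filtered:
        raise SequenceError(
            f"sequence {seq_id!r}: no standard residues remain after sanitation"
        )
    return ProteinSequence(id=seq_id, residues=filtered)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into raw (unsanitized) records.

    Residue strings are uppercased but otherwise untouched, so records with
    nonstandard residues must still pass through :func:`sanitize` before
    descriptor computation. ``ProteinSequence`` validation is bypassed here
    on purpose: parsing and sanitation are separate steps.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SequenceError
        If the file holds no records or ids are duplicated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        obj = object.__new__(ProteinSequence)
        object.__setattr__(obj, "id", rec.id)
        object.__setattr__(obj, "residues", str(rec.seq).upper())
        records.append(obj)
    if not records:
        raise SequenceError(f"no records in FASTA file: {path}")
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA with lines wrapped at ``width``."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


@dataclass
class LabeledDataset:
    """Sequences paired with T/NT labels, keyed by unique sequence id."""

    records: list[tuple[ProteinSequence, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [seq.id for seq, _ in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate ids in labeled dataset: {dupes}")
        for _, label in self.records:
            if label not in VALID_LABELS:
                raise SequenceError(f"invalid label {label!r}; expected T or NT")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[ProteinSequence, str]]:
        return iter(self.records)

    @property
    def sequences(self) -> list[ProteinSequence]:
        return [seq for seq, _ in self.records]

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.records]

    def count(self, label: str) -> int:
        return sum(1 for _, lab in self.records if lab == label)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` table (T/NT), ignoring blank lines."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label table not found: {path}")
    labels: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            seq_id, label = parts
            if label not in VALID_LABELS:
                raise SequenceError(f"{path}:{lineno}: invalid label {label!r}")
            if seq_id in labels:
                raise SequenceError(f"{path}:{lineno}: duplicate id {seq_id!r}")
            labels[seq_id] = label
    return labels


def write_label_table(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for seq_id, label in labels.items():
            fh.write(f"{seq_id}\t{label}\n")


def load_labeled_dataset(fasta_path: str | Path, label_path: str | Path) -> LabeledDataset:
    """Load and sanitize a FASTA + label-table pair into a LabeledDataset.

    Every FASTA record must have a label; extra label rows are ignored.
    """
    raw = read_fasta(fasta_path)
    labels = read_label_table(label_path)
    records = []
    for rec in raw:
        if rec.id not in labels:
            raise SequenceError(f"no label for sequence {rec.id!r}")
        records.append((sanitize(rec.residues, rec.id), labels[rec.id]))
    return LabeledDataset(records)
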