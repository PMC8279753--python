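"""Reading and writing labeled peptide datasets in FASTA.

The benchmark sets this package targets (e.g. ACP740, ACP240) distribute
experimentally verified anticancer peptides (ACPs, the positive class) and
antimicrobial peptides without anticancer activity (the negative class) as
plain FASTA.  Because the on-disk label encoding of such collections varies,
three label conventions are supported:

``two-file``
    positives and negatives live in separate FASTA files (the default —
    upstream repositories usually ship the classes separably);
``header-token``
    a single file whose positive records carry a marker substring in the
    header (default ``"ACP"``, not preceded/followed by ``"non"``);
``sidecar-table``
    a single FASTA plus a 2-column TSV mapping record id to label ``1``/``0``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("acpda")

#: The 20 standard residues in alphabetical one-letter order.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Padding letter; a first-class alphabet member throughout the package.
PAD_RESIDUE = "X"
#: Full sequence alphabet.
ALPHABET = frozenset(STANDARD_RESIDUES + PAD_RESIDUE)


class AcpdaError(Exception):
    """Base class for package errors."""


class FormatError(AcpdaError):
    """Malformed input file (empty file, record without sequence, ...)."""


class ValidationError(AcpdaError):
    """Input violates a domain invariant (alphabet, duplicate ids, ...)."""


class LabelingError(AcpdaError):
    """Records could not be assigned a class label."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified, optionally labeled amino-acid sequence.

    ``sequence`` is a string over the 20 standard residues plus the padding
    letter ``X``; ``label`` is ``1`` for anticancer peptides (ACP), ``0`` for
    non-ACP, or ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = sorted(set(self.sequence) - ALPHABET)
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains illegal characters "
                f"{', '.join(repr(c) for c in bad)}; allowed: 20 standard "
                f"residues plus '{PAD_RESIDUE}'"
            )
        if self.label not in (None, 0, 1):
            raise ValidationError(f"record {self.id!r}: label must be 0, 1 or None")


@dataclass(frozen=True)
class LabeledDataset:
    """Ordered collection of peptide records, every one carrying a label."""

    records: tuple[PeptideRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if any(r.label is None for r in self.records):
            missing = [r.id for r in self.records if r.label is None]
            raise LabelingError(f"unlabeled records: {missing}")
        _check_unique_ids(self.records)

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _check_unique_ids(records: Sequence[PeptideRecord]) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for r in records:
        if r.id in seen:
            dupes.append(r.id)
        seen.add(r.id)
    if dupes:
        raise ValidationError(f"duplicate record ids: {sorted(set(dupes))}")


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptide records from a FASTA file.

    Multi-line sequences are concatenated, residues are upper-cased
    (lower-case input is tolerated with a warning), and any character outside
    the 21-letter alphabet raises :class:`ValidationError` naming the record
    and the offending characters.  Duplicate ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[PeptideRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.warning(
                "record %r: lower-case residues upper-cased on input", rec.id
            )
            seq = seq.upper()
        records.append(PeptideRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records to plain unwrapped FASTA (inverse of :func:`read_fasta`)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV ``id<TAB>label`` with label in {1, 0}."""
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2 or row[1] not in ("0", "1"):
                raise FormatError(f"bad label-table row {row!r} in {path}")
            labels[row[0]] = int(row[1])
    return labels


def write_label_table(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for r in dataset:
            w.writerow([r.id, r.label])


def load_labeled_dataset(
    path: str | Path,
    label_convention: str = "two-file",
    *,
    negative_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    positive_marker: str = "ACP",
) -> LabeledDataset:
    """Load a labeled peptide dataset under one of three label conventions.

    Parameters
    ----------
    path
        FASTA file; under ``two-file`` this is the positive-class file.
    label_convention
        ``"two-file"`` (default), ``"header-token"`` or ``"sidecar-table"``.
    negative_path
        Negative-class FASTA, required for ``two-file``.
    labels_path
        id→label TSV, required for ``sidecar-table``.
    positive_marker
        Header substring marking positives under ``header-token``; a record
        is positive when the marker occurs and is not part of a ``non…``
        token (so ``nonACP`` headers are negative).
    """
    if label_convention == "two-file":
        if negative_path is None:
            raise ValueError("two-file convention requires negative_path")
        pos = [replace(r, label=1) for r in read_fasta(path)]
        neg = [replace(r, label=0) for r in read_fasta(negative_path)]
        return LabeledDataset(tuple(pos + neg))

    if label_convention == "header-token":
        records = read_fasta(path)
        labeled = []
        for r in records:
            is_pos = positive_marker in r.id and f"non{positive_marker}" not in r.id
            labeled.append(replace(r, label=1 if is_pos else 0))
        return LabeledDataset(tuple(labeled))

    if label_convention == "sidecar-table":
        if labels_path is None:
            raise ValueError("sidecar-table convention requires labels_path")
        records = read_fasta(path)
        table = read_label_table(labels_path)
        unmatched = [r.id for r in records if r.id not in table]
        if unmatched:
            raise LabelingError(f"records with no label-table entry: {unmatched}")
        return LabeledDataset(tuple(replace(r, label=table[r.id]) for r in records))

    raise ValueError(
        f"unknown label convention {label_convention!r}; expected "
        "'two-file', 'header-token' or 'sidecar-table'"
    )
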