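"""Numeric feature encodings for normalized peptides.

Three encodings, concatenated in the fixed order ``bpf | aaindex | kmer``:

* **BPF** (binary profile features): positional one-hot encoding of the first
  ``k`` N-terminal residues over the alphabetical 20-letter alphabet; ``X``
  maps to the all-zero vector.  Dimension ``20*k`` (140 for the default k=7).
* **AAindex**: per-position physicochemical index values — for each position
  the full column of the index table for that residue, position-major.
  Dimension ``L_X * n_indices`` (21,240 for L_X=40 with the 531-index table).
* **k-mer sparse matrix**: the peptide is rewritten over a 7-class reduced
  alphabet and turned into a 0/1 occurrence matrix of shape
  ``7**K x (L-K+1)`` (one column per window, a single 1 at the row of the
  window's class k-mer); the matrix is compressed to a fixed ``7**K`` vector
  by the leading singular triplet, sigma_1 * u_1.

The AAindex block is emitted in full here; selection of the most informative
indices is a downstream, fold-local step (see ``feature_select``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io_datasets import (
    LabeledDataset,
    PAD_RESIDUE,
    STANDARD_RESIDUES,
    ValidationError,
)
from .preprocess import normalize_length

BLOCK_TAGS = ("bpf", "aaindex", "kmer")

#: Default 7-class reduced alphabet (a standard physicochemical grouping:
#: small/aliphatic, large hydrophobic, polar-uncharged, amide/aromatic-polar,
#: basic, acidic, cysteine).  Configurable via :class:`KmerConfig`.
DEFAULT_KMER_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

_RESIDUE_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


# ---------------------------------------------------------------------------
# AAindex table


@dataclass(frozen=True)
class AAIndexTable:
    """Per-residue physicochemical index values (index x residue matrix).

    ``values`` has one row per index and one column per standard residue, in
    the alphabetical residue order used throughout the package.  Tables must
    be gap-free (indices with missing values are excluded at build time).
    """

    index_ids: tuple[str, ...]
    values: np.ndarray  # (n_indices, 20) float

    def __post_init__(self) -> None:
        object.__setattr__(self, "index_ids", tuple(self.index_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape != (len(self.index_ids), 20):
            raise ValidationError(
                f"AAindex table shape {values.shape} does not match "
                f"({len(self.index_ids)}, 20)"
            )
        if not np.isfinite(values).all():
            raise ValidationError("AAindex table contains missing/non-finite values")

    @property
    def n_indices(self) -> int:
        return len(self.index_ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAIndexTable":
        """Read a table from TSV: header ``index_id`` + 20 residue columns."""
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[1:] != list(STANDARD_RESIDUES):
                raise ValidationError(
                    f"AAindex TSV {path}: residue columns must be "
                    f"{' '.join(STANDARD_RESIDUES)} in order"
                )
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(tuple(ids), np.array(rows, dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("index_id\t" + "\t".join(STANDARD_RESIDUES) + "\n")
            for iid, row in zip(self.index_ids, self.values):
                fh.write(iid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def synthetic_aaindex_table(n_indices: int = 531, seed: int = 20210630) -> AAIndexTable:
    """Deterministic **synthetic** stand-in for a real AAindex table.

    Entries are i.i.d. standard normal draws from a fixed seed.  Such a table
    carries no physicochemical meaning: each index is simply a random
    injective embedding of the 20 residues, so the AAindex block becomes a
    dense random re-encoding of per-position residue identity.  That is
    sufficient for every structural property of the pipeline (dimensions,
    selection, augmentation, learning positional composition signals); a real
    gap-free 531x20 table can be substituted via :meth:`AAIndexTable.from_tsv`
    wherever physicochemical interpretability matters.
    """
    rng = np.random.default_rng(seed)
    ids = tuple(f"SYN{i:04d}" for i in range(n_indices))
    return AAIndexTable(ids, rng.standard_normal((n_indices, 20)))


_DEFAULT_TABLE: AAIndexTable | None = None


def default_aaindex_table() -> AAIndexTable:
    """The package default table (531 synthetic indices, cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = synthetic_aaindex_table()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# Feature matrix container


@dataclass
class FeatureMatrix:
    """Samples x features table with per-feature block tags and labels.

    ``blocks`` tags every feature with ``bpf``, ``aaindex`` or ``kmer``;
    ``labels`` is an optional per-sample binary class vector; ``provenance``
    optionally records, for augmented rows, the id of the source sample
    (``None`` for original rows).
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    blocks: tuple[str, ...]
    labels: np.ndarray | None = None
    provenance: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.feature_names = tuple(self.feature_names)
        self.blocks = tuple(self.blocks)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.feature_names)})"
            )
        if len(self.blocks) != len(self.feature_names):
            raise ValidationError("blocks must have one tag per feature")
        unknown = set(self.blocks) - set(BLOCK_TAGS)
        if unknown:
            raise ValidationError(f"unknown block tags: {sorted(unknown)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValidationError("labels must have one entry per sample")
        if self.provenance is not None:
            self.provenance = tuple(self.provenance)
            if len(self.provenance) != len(self.sample_ids):
                raise ValidationError("provenance must have one entry per sample")
        bpf_cols = self.values[:, self.block_mask("bpf")]
        if bpf_cols.size and not np.isin(bpf_cols, (0.0, 1.0)).all():
            raise ValidationError("bpf-tagged columns must contain only 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def block_mask(self, tag: str) -> np.ndarray:
        return np.array([b == tag for b in self.blocks], dtype=bool)

    def subset_samples(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            feature_names=self.feature_names,
            values=self.values[idx],
            blocks=self.blocks,
            labels=None if self.labels is None else self.labels[idx],
            provenance=None
            if self.provenance is None
            else tuple(self.provenance[i] for i in idx),
        )

    def fingerprint(self) -> str:
        """Stable hash of the sample ids (used to tie fitted models to data)."""
        h = hashlib.sha256("\n".join(self.sample_ids).encode())
        return h.hexdigest()[:16]

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with a ``#blocks`` header line.

        Columns: ``sample_id``, ``label`` (empty if absent), ``source``
        (augmentation provenance, ``-`` for originals), then one column per
        feature.
        """
        with open(path, "w") as fh:
            fh.write("#blocks\t\t\t" + "\t".join(self.blocks) + "\n")
            fh.write("sample_id\tlabel\tsource\t" + "\t".join(self.feature_names) + "\n")
            for i, sid in enumerate(self.sample_ids):
                label = "" if self.labels is None else str(int(self.labels[i]))
                src = "-"
                if self.provenance is not None and self.provenance[i] is not None:
                    src = self.provenance[i]
                row = "\t".join(repr(float(v)) for v in self.values[i])
                fh.write(f"{sid}\t{label}\t{src}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            blocks_line = fh.readline().rstrip("\n").split("\t")
            if blocks_line[0] != "#blocks":
                raise ValidationError(f"{path}: missing '#blocks' header line")
            blocks = tuple(blocks_line[3:])
            names = tuple(fh.readline().rstrip("\n").split("\t")[3:])
            sids, labels, prov, rows = [], [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                sids.append(parts[0])
                labels.append(parts[1])
                prov.append(None if parts[2] == "-" else parts[2])
                rows.append([float(x) for x in parts[3:]])
        has_labels = all(l != "" for l in labels)
        return cls(
            sample_ids=tuple(sids),
            feature_names=names,
            values=np.array(rows, dtype=float),
            blocks=blocks,
            labels=np.array([int(l) for l in labels]) if has_labels else None,
            provenance=tuple(prov) if any(p is not None for p in prov) else None,
        )


# ---------------------------------------------------------------------------
# Binary profile features


def encode_bpf(sequence: str, k: int = 7) -> np.ndarray:
    """One-hot encode the first ``k`` N-terminal residues (20*k features).

    Residue ``r`` at position ``j`` sets entry ``20*j + index(r)`` where the
    index runs over the alphabetical order A,C,D,...,Y; the padding letter
    ``X`` contributes an all-zero 20-vector.
    """
    if len(sequence) < k:
        raise ValidationError(
            f"sequence length {len(sequence)} < BPF window k={k}"
        )
    out = np.zeros(20 * k)
    for j, r in enumerate(sequence[:k]):
        if r != PAD_RESIDUE:
            out[20 * j + _RESIDUE_INDEX[r]] = 1.0
    return out


def bpf_feature_names(k: int = 7) -> list[str]:
    return [
        f"bpf_pos{j}_{r}" for j in range(k) for r in STANDARD_RESIDUES
    ]


# ---------------------------------------------------------------------------
# AAindex encoding


def encode_aaindex(sequence: str, table: AAIndexTable) -> np.ndarray:
    """Position-major physicochemical encoding: for each position the full
    column of index values of its residue; ``X`` contributes zeros.

    Output length is ``len(sequence) * table.n_indices``; the sequence must
    already be normalized to the configured ``L_X``.
    """
    cols = np.array(
        [-1 if r == PAD_RESIDUE else _RESIDUE_INDEX[r] for r in sequence], dtype=int
    )
    out = table.values.T[cols]  # (L, n_indices); row for X is garbage, zero it
    out[cols == -1] = 0.0
    return out.reshape(-1)


def aaindex_feature_names(l_x: int, table: AAIndexTable) -> list[str]:
    return [f"aai_pos{j}_{iid}" for j in range(l_x) for iid in table.index_ids]


# ---------------------------------------------------------------------------
# k-mer sparse matrix + SVD reduction


@dataclass(frozen=True)
class KmerConfig:
    """k-mer length and reduced-alphabet partition (7 disjoint groups
    covering the 20 residues by default, giving ``7**K`` possible k-mers)."""

    k: int = 3
    alphabet_classes: tuple[str, ...] = DEFAULT_KMER_CLASSES

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k-mer length must be >= 1, got {self.k}")
        joined = "".join(self.alphabet_classes)
        if sorted(joined) != sorted(STANDARD_RESIDUES):
            raise ValidationError(
                "alphabet classes must partition the 20 standard residues"
            )

    @property
    def n_classes(self) -> int:
        return len(self.alphabet_classes)

    @property
    def n_kmers(self) -> int:
        return self.n_classes ** self.k

    def residue_class(self) -> dict[str, int]:
        return {
            r: ci for ci, group in enumerate(self.alphabet_classes) for r in group
        }


def build_kmer_matrix(sequence: str, config: KmerConfig | None = None) -> sp.csc_matrix:
    """0/1 occurrence matrix of shape ``(n_classes**K, L-K+1)``.

    Column ``t`` has a single 1 at the row indexing the reduced-alphabet
    k-mer starting at position ``t`` (row index = the K class labels read as
    a mixed-radix number, most significant first).  Windows containing the
    padding letter ``X`` produce all-zero columns: padding must not create
    spurious k-mers.
    """
    config = config or KmerConfig()
    L, K = len(sequence), config.k
    if L < K:
        raise ValidationError(f"sequence length {L} < k-mer length {K}")
    cls = config.residue_class()
    n_cols = L - K + 1
    rows, cols = [], []
    for t in range(n_cols):
        window = sequence[t : t + K]
        if PAD_RESIDUE in window:
            continue
        idx = 0
        for r in window:
            idx = idx * config.n_classes + cls[r]
        rows.append(idx)
        cols.append(t)
    data = np.ones(len(rows))
    return sp.csc_matrix(
        (data, (rows, cols)), shape=(config.n_kmers, n_cols)
    )


def svd_reduce_kmer(M: sp.spmatrix) -> np.ndarray:
    """Compress a k-mer matrix to a fixed-length vector: sigma_1 * u_1.

    The leading left singular vector scaled by the leading singular value,
    with the sign fixed so the entry of largest magnitude (lowest index on
    ties) is positive.  Output length equals the row count of ``M``.
    Homogeneous: scaling ``M`` by c > 0 scales the output by c.

    The decomposition runs dense (LAPACK): k-mer matrices are small
    (343 x ~O(60) for the defaults) and iterative sparse solvers are
    start-vector dependent when the leading singular value is degenerate —
    which happens whenever all windows of a peptide are distinct k-mers —
    whereas the dense route is bit-reproducible.
    """
    M = sp.csc_matrix(M)
    if M.nnz == 0:
        raise ValidationError("svd_reduce_kmer: all-zero k-mer matrix")
    u, s, _ = np.linalg.svd(M.toarray(), full_matrices=False)
    vec = s[0] * u[:, 0]
    pivot = np.argmax(np.abs(vec))
    if vec[pivot] < 0:
        vec = -vec
    return vec


def kmer_feature_names(config: KmerConfig | None = None) -> list[str]:
    config = config or KmerConfig()
    names = []
    for idx in range(config.n_kmers):
        digits, x = [], idx
        for _ in range(config.k):
            digits.append(x % config.n_classes)
            x //= config.n_classes
        names.append("kmer_" + "".join(str(d) for d in reversed(digits)))
    return names


# ---------------------------------------------------------------------------
# Dataset-level encoding


def encode_dataset(
    dataset: LabeledDataset,
    l_x: int,
    feature_set: Sequence[str] = ("bpf", "aaindex"),
    table: AAIndexTable | None = None,
    kmer_config: KmerConfig | None = None,
    bpf_k: int = 7,
) -> FeatureMatrix:
    """Encode every record into the concatenation ``bpf | aaindex | kmer``
    (whichever blocks are requested), after length normalization to ``l_x``.

    The aaindex block is the full (unselected) block; mRMR selection is a
    separate, training-fold-local step.
    """
    feature_set = tuple(feature_set)
    if not feature_set:
        raise ValueError("feature_set must be non-empty")
    unknown = set(feature_set) - set(BLOCK_TAGS)
    if unknown:
        raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
    table = table or default_aaindex_table()
    kmer_config = kmer_config or KmerConfig()

    names: list[str] = []
    blocks: list[str] = []
    if "bpf" in feature_set:
        bn = bpf_feature_names(bpf_k)
        names += bn
        blocks += ["bpf"] * len(bn)
    if "aaindex" in feature_set:
        an = aaindex_feature_names(l_x, table)
        names += an
        blocks += ["aaindex"] * len(an)
    if "kmer" in feature_set:
        kn = kmer_feature_names(kmer_config)
        names += kn
        blocks += ["kmer"] * len(kn)

    rows = np.empty((len(dataset), len(names)))
    for i, rec in enumerate(dataset):
        seq = normalize_length(rec.sequence, l_x)
        parts = []
        if "bpf" in feature_set:
            parts.append(encode_bpf(seq, bpf_k))
        if "aaindex" in feature_set:
            parts.append(encode_aaindex(seq, table))
        if "kmer" in feature_set:
            parts.append(svd_reduce_kmer(build_kmer_matrix(seq, kmer_config)))
        rows[i] = np.concatenate(parts)

    return FeatureMatrix(
        sample_ids=tuple(r.id for r in dataset),
        feature_names=tuple(names),
        values=rows,
        blocks=tuple(blocks),
        labels=np.array([r.label for r in dataset], dtype=int),
    )
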