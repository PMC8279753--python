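"""Length normalization of peptides to a fixed length ``L_X``.

Per-position encoders (the AAindex block in particular) require equal-length
inputs.  Shorter peptides are padded at the C-terminus with the letter ``X``;
longer peptides are truncated, keeping the N-terminus — the method's
positional features (binary profile of the first seven residues) are
N-anchored, so the N-terminus is the informative end.  ``L_X`` is typically
chosen from {40, 50, 60}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace

from .io_datasets import LabeledDataset, PAD_RESIDUE


def normalize_length(sequence: str, l_x: int) -> str:
    """Pad with ``X`` or truncate so the result has length exactly ``l_x``.

    Idempotent, and either the input is a prefix of the output (padding) or
    the output a prefix of the input (truncation).
    """
    if l_x < 1:
        raise ValueError(f"L_X must be >= 1, got {l_x}")
    if len(sequence) < l_x:
        return sequence + PAD_RESIDUE * (l_x - len(sequence))
    return sequence[:l_x]


def normalize_dataset(dataset: LabeledDataset, l_x: int) -> LabeledDataset:
    """Apply :func:`normalize_length` to every record."""
    return LabeledDataset(
        tuple(replace(r, sequence=normalize_length(r.sequence, l_x)) for r in dataset)
    )


def length_histogram(dataset: LabeledDataset) -> dict[int, int]:
    """Map sequence length -> record count; counts sum to ``len(dataset)``."""
    if len(dataset) == 0:
        raise ValueError("length_histogram requires a non-empty dataset")
    return dict(Counter(len(r.sequence) for r in dataset))


def write_length_histogram(dataset: LabeledDataset, path) -> None:
    """Export the histogram as 2-column TSV (length, count), sorted by length."""
    hist = length_histogram(dataset)
    with open(path, "w") as fh:
        fh.write("length\tcount\n")
        for length in sorted(hist):
            fh.write(f"{length}\t{hist[length]}\n")
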