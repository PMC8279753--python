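"""Synthetic labeled peptide datasets with a controllable class signal.

The generator emulates the shape of anticancer-peptide benchmarks — a few
hundred peptides per class, lengths roughly 10–60 residues — with a tunable
N-terminal compositional bias separating the classes.  Negatives are i.i.d.
uniform over the 20 standard residues.  Positives mix, per N-terminal
position, an enriched distribution concentrated on the cationic/hydrophobic
set {K, R, L, F, A} (mimicking cationic amphipathic ACPs; a modeling choice
for tests, not a biological claim) with the uniform background.  The signal
sits at the N-terminus deliberately so both the positional one-hot (bpf)
block and the per-position physicochemical (aaindex) block can detect it.

A direct Gaussian feature-matrix fixture is also provided for exercising
feature selection and augmentation without going through sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import FeatureMatrix
from .io_datasets import LabeledDataset, PeptideRecord, STANDARD_RESIDUES

#: Enriched N-terminal residues for the positive class.
ENRICHED_RESIDUES = "KRLFA"
#: Number of N-terminal positions carrying the signal (the bpf window).
SIGNAL_POSITIONS = 7


@dataclass(frozen=True)
class SyntheticSpec:
    """Class sizes, length range, N-terminal signal strength in [0, 1], seed."""

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (10, 60)
    signal_strength: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < SIGNAL_POSITIONS or hi < lo:
            raise ValueError(
                f"length_range must satisfy {SIGNAL_POSITIONS} <= min <= max "
                f"(bpf needs {SIGNAL_POSITIONS} N-terminal residues)"
            )
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled dataset per the spec; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    residues = np.array(list(STANDARD_RESIDUES))
    enriched = np.array(list(ENRICHED_RESIDUES))
    lo, hi = spec.length_range

    records: list[PeptideRecord] = []
    for label, n, tag in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = rng.choice(residues, size=length)
            if label == 1:
                head = min(SIGNAL_POSITIONS, length)
                use_signal = rng.random(head) < spec.signal_strength
                enriched_draw = rng.choice(enriched, size=head)
                seq[:head] = np.where(use_signal, enriched_draw, seq[:head])
            records.append(
                PeptideRecord(id=f"syn_{tag}_{i}", sequence="".join(seq), label=label)
            )
    return LabeledDataset(tuple(records))


def generate_feature_fixture(
    n_samples: int,
    d_signal: int,
    d_noise: int,
    effect_size: float,
    seed: int | None = None,
    bpf_width: int = 0,
) -> FeatureMatrix:
    """Gaussian feature fixture: ``d_signal`` class-shifted columns (positive
    class mean = ``effect_size``, negative 0, unit variance) followed by
    ``d_noise`` standard-normal columns, all tagged ``aaindex``; optionally a
    random binary block of ``bpf_width`` columns prepended, tagged ``bpf``.

    Labels alternate balanced (ceil(n/2) positives).
    """
    if d_signal + d_noise < 1:
        raise ValueError("need at least one feature column")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    n_pos = (n_samples + 1) // 2
    labels = np.array([1] * n_pos + [0] * (n_samples - n_pos))

    cols = rng.standard_normal((n_samples, d_signal + d_noise))
    cols[labels == 1, :d_signal] += effect_size
    names = [f"aai_sig{j}" for j in range(d_signal)] + [
        f"aai_noise{j}" for j in range(d_noise)
    ]
    blocks = ["aaindex"] * (d_signal + d_noise)
    if bpf_width:
        bin_block = rng.integers(0, 2, size=(n_samples, bpf_width)).astype(float)
        cols = np.hstack([bin_block, cols])
        names = [f"bpf_rand{j}" for j in range(bpf_width)] + names
        blocks = ["bpf"] * bpf_width + blocks
    return FeatureMatrix(
        sample_ids=tuple(f"fx_{i}" for i in range(n_samples)),
        feature_names=tuple(names),
        values=cols,
        blocks=tuple(blocks),
        labels=labels,
    )
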