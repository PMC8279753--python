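import numpy as np
import pytest

from acpda import (
    FeatureMatrix,
    LabeledDataset,
    PeptideRecord,
)


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Five labeled peptides of varying length (>= 7 residues each)."""
    return LabeledDataset(
        (
            PeptideRecord("p1", "FAKLLKVAGKL", 1),
            PeptideRecord("p2", "KRKRLLAFAKK", 1),
            PeptideRecord("p3", "GIGAVLKVLTTGLPALIS", 0),
            PeptideRecord("p4", "DEDEDEDHNQW", 0),
            PeptideRecord("p5", "YMTSCCHNQWVV", 0),
        )
    )


@pytest.fixture
def labeled_matrix() -> FeatureMatrix:
    """Small labeled matrix with a bpf block and an aaindex block."""
    rng = np.random.default_rng(42)
    n = 12
    bpf = rng.integers(0, 2, size=(n, 4)).astype(float)
    aai = rng.standard_normal((n, 6)) + 3.0  # positive-shifted, away from zero
    return FeatureMatrix(
        sample_ids=tuple(f"s{i}" for i in range(n)),
        feature_names=("b0", "b1", "b2", "b3", "a0", "a1", "a2", "a3", "a4", "a5"),
        values=np.hstack([bpf, aai]),
        blocks=("bpf",) * 4 + ("aaindex",) * 6,
        labels=np.array([1, 0] * (n // 2)),
    )


def write_fasta_text(path, text: str) -> str:
    path.write_text(text)
    return str(path)
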