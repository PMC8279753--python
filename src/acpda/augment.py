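"""Feature-space data augmentation by masked multiplicative perturbation.

Small peptide benchmarks starve the classifier of training samples.
Noise-adding oversampling generates pseudosamples directly in feature space:
a source row F_i is drawn uniformly with replacement from one class of the
training split, a perturbation vector V is drawn fresh for it, and the
pseudosample is

    F_new = F_i  *elementwise*  (1 + a * V)

with ``a`` a small coefficient (default 0.005).  V is zero on the binary
(bpf) columns — a 0/1 profile cannot absorb noise, so pseudosamples copy the
source's bpf block bit-for-bit — and i.i.d. uniform on [0, 1) on the aaindex
columns, so every aaindex entry moves by a relative amount in [0, a) away
from zero (kmer columns, when present, are likewise copied unchanged).

Each class is augmented independently and only ever on the training split,
after feature selection, in the selected (e.g. 140 + 50 = 190 dimensional)
space.  Pseudosample counts are a fraction of the class size (the sweep uses
100/200/300%).  The whole procedure is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoders import FeatureMatrix
from .io_datasets import ValidationError


@dataclass(frozen=True)
class AugmentationConfig:
    """Perturbation coefficient ``a``, pseudosample fraction ``n_fraction``
    (1.0 = one pseudosample per original class member), and seed."""

    a: float = 0.005
    n_fraction: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValidationError(f"perturbation coefficient a must be >= 0, got {self.a}")
        if self.n_fraction < 0:
            raise ValidationError(f"n_fraction must be >= 0, got {self.n_fraction}")


def make_perturbation_vector(
    bpf_width: int, aaindex_width: int, rng: np.random.Generator
) -> np.ndarray:
    """V: zeros over the bpf block, then i.i.d. uniform [0, 1) over aaindex."""
    if bpf_width < 0 or aaindex_width < 0:
        raise ValueError("widths must be >= 0")
    return np.concatenate([np.zeros(bpf_width), rng.random(aaindex_width)])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def augment_class(
    X_class: np.ndarray,
    config: AugmentationConfig,
    block_tags: Sequence[str],
    rng: np.random.Generator,
    source_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Generate ``round(n_fraction * n)`` pseudosamples for one class.

    Returns the pseudosample rows and, for provenance, the source row index
    of each.  Only aaindex-tagged columns are perturbed; all other columns
    are exact copies of the source row.
    """
    X_class = np.asarray(X_class, dtype=float)
    if X_class.ndim != 2 or X_class.shape[0] == 0:
        raise ValidationError("augment_class requires a non-empty 2-D class matrix")
    block_tags = list(block_tags)
    if len(block_tags) != X_class.shape[1]:
        raise ValidationError("block_tags must have one tag per column")
    unknown = set(block_tags) - {"bpf", "aaindex", "kmer"}
    if unknown:
        raise ValidationError(f"unknown block tags: {sorted(unknown)}")
    perturb_mask = np.array([t == "aaindex" for t in block_tags])

    n = X_class.shape[0]
    n_new = _round_half_up(config.n_fraction * n)
    rows = np.empty((n_new, X_class.shape[1]))
    sources: list[int] = []
    for j in range(n_new):
        i = int(rng.integers(n))
        v = np.zeros(X_class.shape[1])
        v[perturb_mask] = rng.random(int(perturb_mask.sum()))
        rows[j] = X_class[i] * (1.0 + config.a * v)
        sources.append(i)
    return rows, sources


def augment_training_set(
    X_train: FeatureMatrix, config: AugmentationConfig
) -> FeatureMatrix:
    """Augment positives and negatives independently with the same config.

    Output rows are the originals followed by the pseudosamples (positives'
    then negatives'), each pseudosample labeled with its class and linked to
    its source sample id via the matrix's ``provenance`` field.  With the
    same ``n_fraction`` applied to both classes the class ratio is preserved.
    """
    if X_train.labels is None:
        raise ValidationError("augment_training_set requires a labeled matrix")
    rng = np.random.default_rng(config.seed)

    new_rows: list[np.ndarray] = []
    new_ids: list[str] = []
    new_labels: list[int] = []
    new_sources: list[str] = []
    for label, tag in ((1, "pos"), (0, "neg")):
        idx = np.flatnonzero(X_train.labels == label)
        if idx.size == 0:
            raise ValidationError(f"cannot augment: class {label} is empty")
        rows, sources = augment_class(
            X_train.values[idx], config, X_train.blocks, rng
        )
        new_rows.append(rows)
        new_ids += [f"aug_{tag}_{j}" for j in range(rows.shape[0])]
        new_labels += [label] * rows.shape[0]
        new_sources += [X_train.sample_ids[idx[i]] for i in sources]

    pseudo = np.vstack(new_rows) if new_rows else np.empty((0, X_train.n_features))
    return FeatureMatrix(
        sample_ids=X_train.sample_ids + tuple(new_ids),
        feature_names=X_train.feature_names,
        values=np.vstack([X_train.values, pseudo]),
        blocks=X_train.blocks,
        labels=np.concatenate([X_train.labels, np.array(new_labels, dtype=int)]),
        provenance=tuple([None] * X_train.n_samples) + tuple(new_sources),
    )
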