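"""mRMR feature selection over the AAindex block.

The full per-position AAindex block (L_X * 531 features for L_X=40) is far
larger than the sample sizes of typical anticancer-peptide benchmarks, so the
``m`` most informative features (default 50) are selected by minimum
redundancy - maximum relevance: greedy forward selection where the first
feature maximizes the mutual information MI(x; y) with the class label and
every subsequent feature maximizes

    MI(x; y) - (1/|S|) * sum_{s in S} MI(x; s)          (MID, the default)

or the quotient variant MI(x; y) / ((1/|S|) sum MI(x; s)) (MIQ).

Continuous features are discretized into 3 bins at mu - sigma and mu + sigma
(a standard mRMR discretization) for MI estimation only; the selection is
then applied to the *raw* columns.  Selection must be fitted on training
data only — the cross-validation driver fits one model per training fold.

Ties in the greedy criterion are broken by lowest feature index, making the
selection fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoders import FeatureMatrix
from .io_datasets import AcpdaError, ValidationError


class SelectionError(AcpdaError):
    """A fitted selection model does not match the matrix it is applied to."""


def discretize_three_bins(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Discretize a feature column into bins [-inf, mu-sigma), [mu-sigma,
    mu+sigma), [mu+sigma, inf) -> labels {0, 1, 2}; returns the edges too."""
    x = np.asarray(x, dtype=float)
    mu, sigma = x.mean(), x.std()
    edges = (mu - sigma, mu + sigma)
    return np.digitize(x, edges), edges


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two discrete vectors.

    Computed from the empirical joint distribution; 0 when the vectors are
    independent in-sample.  A constant ``y`` has zero entropy and cannot
    carry class information — rejected as degenerate.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have the same length >= 2")
    if np.unique(y).size < 2:
        raise ValidationError("degenerate labels: y is constant")
    return _mi_pairwise(x, y)


def _mi_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xv.size, yv.size))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def _mi_against_all(onehots: list[np.ndarray], z: np.ndarray) -> np.ndarray:
    """MI (nats) between a discrete vector ``z`` and every column of a
    discretized matrix, vectorized via indicator-matrix products.

    ``onehots[a]`` is the (n, p) float32 indicator of column value ``a``.
    """
    n, p = onehots[0].shape
    zv, zi = np.unique(z, return_inverse=True)
    mi = np.zeros(p)
    # joint counts C[a][b][j] = #{i : D[i, j] == a and z[i] == b}
    z_ind = [(zi == b).astype(np.float32) for b in range(zv.size)]
    # float32 products yield exact integer counts (n << 2**24); the
    # probability arithmetic then runs in float64
    counts = [
        [(z_ind[b] @ onehots[a]).astype(np.float64) for b in range(zv.size)]
        for a in range(len(onehots))
    ]
    pa = [c.sum(axis=0, dtype=np.float64) / n for c in onehots]  # P(D==a)
    pb = [float(zi_b.sum()) / n for zi_b in z_ind]  # P(z==b)
    for a in range(len(onehots)):
        for b in range(zv.size):
            pab = counts[a][b] / n
            denom = pa[a] * pb[b]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pab * np.log(pab / denom)
            mi += np.where(pab > 0, term, 0.0)
    return mi


@dataclass(frozen=True)
class SelectionModel:
    """A fitted mRMR selection: ordered feature names, the bin edges used for
    MI estimation, and a fingerprint of the training samples it was fit on."""

    selected_names: tuple[str, ...]
    m: int
    discretization: dict[str, tuple[float, float]]
    fit_fingerprint: str
    scheme: str = "MID"

    def __post_init__(self) -> None:
        if len(self.selected_names) != self.m:
            raise ValidationError("selected_names length must equal m")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_names": list(self.selected_names),
                    "m": self.m,
                    "discretization": {k: list(v) for k, v in self.discretization.items()},
                    "fit_fingerprint": self.fit_fingerprint,
                    "scheme": self.scheme,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected_names=tuple(d["selected_names"]),
            m=d["m"],
            discretization={k: tuple(v) for k, v in d["discretization"].items()},
            fit_fingerprint=d["fit_fingerprint"],
            scheme=d.get("scheme", "MID"),
        )


def fit_mrmr(
    X: FeatureMatrix,
    m: int,
    scheme: str = "MID",
    block: str = "aaindex",
) -> SelectionModel:
    """Greedy mRMR selection of ``m`` features from the ``block``-tagged
    columns of ``X`` (labels must be present).

    Deterministic: argmax ties go to the lowest feature index.
    """
    if X.labels is None:
        raise ValidationError("fit_mrmr requires a labeled matrix")
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    mask = X.block_mask(block)
    names = [n for n, keep in zip(X.feature_names, mask) if keep]
    if m > len(names):
        raise ValueError(f"m={m} exceeds the {len(names)} {block} features")
    y = X.labels
    if np.unique(y).size < 2:
        raise ValidationError("degenerate labels: need both classes to fit mRMR")
    cols = X.values[:, mask]
    n, p = cols.shape

    edges: dict[str, tuple[float, float]] = {}
    mu = cols.mean(axis=0)
    sigma = cols.std(axis=0)
    lo, hi = mu - sigma, mu + sigma
    # same boundary convention as discretize_three_bins (x >= edge moves up)
    disc = (cols >= lo[None, :]).astype(np.int8) + (cols >= hi[None, :]).astype(np.int8)
    for j, name in enumerate(names):
        edges[name] = (float(lo[j]), float(hi[j]))

    onehots = [(disc == a).astype(np.float32) for a in (0, 1, 2)]
    relevance = _mi_against_all(onehots, y)

    selected: list[int] = []
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    for _ in range(m):
        if not selected:
            score = relevance.copy()
        else:
            red_mean = red_sum / len(selected)
            if scheme == "MID":
                score = relevance - red_mean
            else:
                score = relevance / np.maximum(red_mean, 1e-12)
        score[~available] = -np.inf
        pick = int(np.argmax(score))  # first max: lowest-index tie-break
        selected.append(pick)
        available[pick] = False
        red_sum += _mi_against_all(onehots, disc[:, pick])

    sel_names = tuple(names[j] for j in selected)
    return SelectionModel(
        selected_names=sel_names,
        m=m,
        discretization={name: edges[name] for name in sel_names},
        fit_fingerprint=X.fingerprint(),
        scheme=scheme,
    )


def apply_selection(X: FeatureMatrix, model: SelectionModel) -> FeatureMatrix:
    """Reduce the aaindex block to the selected columns, in model order;
    bpf/kmer blocks pass through untouched (fixed order bpf | aaindex | kmer).

    Selection indexes the raw feature values — the discretization used during
    fitting is never applied to the data.  Idempotent.
    """
    name_to_col = {n: j for j, n in enumerate(X.feature_names)}
    missing = [n for n in model.selected_names if n not in name_to_col]
    if missing:
        raise SelectionError(
            f"matrix lacks {len(missing)} selected feature(s) (e.g. "
            f"{missing[:3]}); model fit_fingerprint={model.fit_fingerprint}"
        )
    keep: list[int] = []
    keep += [j for j, b in enumerate(X.blocks) if b == "bpf"]
    keep += [name_to_col[n] for n in model.selected_names]
    keep += [j for j, b in enumerate(X.blocks) if b == "kmer"]
    return FeatureMatrix(
        sample_ids=X.sample_ids,
        feature_names=tuple(X.feature_names[j] for j in keep),
        values=X.values[:, keep],
        blocks=tuple(X.blocks[j] for j in keep),
        labels=X.labels,
        provenance=X.provenance,
    )
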