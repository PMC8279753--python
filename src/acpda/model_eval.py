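"""Classifier training, five-fold cross-validated evaluation, and the
parameter sweep / feature ablation / classifier comparison experiments.

The evaluation protocol is strict about leakage: within each stratified
fold, mRMR feature selection is fitted on the training split only, data
augmentation generates pseudosamples from training rows only (a runtime
guard asserts that no test sample ever serves as an augmentation source),
and the test split is scored untouched.

Five metrics are reported as percentages from the per-fold confusion counts:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    PRE = TP / (TP + FP)
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as NaN (undefined), never
silently as 0.  Aggregates are unweighted means over folds, ignoring
undefined folds.  MCC, the balanced criterion, drives model selection in
the sweep.

The MLP default mirrors the reference configuration: 6 hidden layers of 100
rectified-linear units, L2 penalty alpha = 0.01, the stochastic (adam)
optimizer at library defaults, seeded.  Features are fed unstandardized by
default; an optional per-fold standardizer exists behind a flag because MLP
convergence on raw feature scales is a known hazard (its use is logged and
echoed in the report config).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .augment import AugmentationConfig, augment_training_set
from .encoders import (
    AAIndexTable,
    FeatureMatrix,
    KmerConfig,
    default_aaindex_table,
    encode_dataset,
)
from .feature_select import apply_selection, fit_mrmr
from .io_datasets import AcpdaError, LabeledDataset, ValidationError

logger = logging.getLogger("acpda")

METRIC_NAMES = ("ACC", "PRE", "SN", "SP", "MCC")
CLASSIFIER_KINDS = ("mlp", "svm", "rf", "dt", "extratrees")
ALL_FEATURE_SETS = (
    ("bpf",),
    ("aaindex",),
    ("kmer",),
    ("bpf", "aaindex"),
    ("bpf", "kmer"),
    ("aaindex", "kmer"),
    ("bpf", "aaindex", "kmer"),
)


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus hyperparameter overrides.

    ``mlp`` defaults to 6 hidden layers x 100 units, relu, alpha=0.01 and a
    fixed seed; the other kinds run at library defaults (seeded where the
    algorithm is stochastic), echoed into the report config.
    """

    kind: str = "mlp"
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(
                f"unknown classifier kind {self.kind!r}; expected one of "
                f"{CLASSIFIER_KINDS}"
            )

    def build(self, seed: int):
        hp = dict(self.hyperparams)
        if self.kind == "mlp":
            params = dict(
                hidden_layer_sizes=(100,) * 6,
                activation="relu",
                alpha=0.01,
                random_state=seed,
            )
            params.update(hp)
            return MLPClassifier(**params)
        if self.kind == "svm":
            return SVC(random_state=seed, **hp)
        if self.kind == "rf":
            return RandomForestClassifier(random_state=seed, **hp)
        if self.kind == "dt":
            return DecisionTreeClassifier(random_state=seed, **hp)
        return ExtraTreesClassifier(random_state=seed, **hp)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five evaluation metrics as percentages; NaN where undefined."""
    if c.total == 0:
        raise ValidationError("compute_metrics requires at least one sample")
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "ACC": ratio(tp + tn, c.total),
        "PRE": ratio(tp, tp + fp),
        "SN": ratio(tp, tp + fn),
        "SP": ratio(tn, tn + fp),
        "MCC": 100.0 * (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
    }


@dataclass
class CVReport:
    """Config echo, per-fold confusion counts and metrics, fold-mean
    aggregate (NaN folds ignored in the mean)."""

    config: dict
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[dict[str, float]]

    @property
    def aggregate(self) -> dict[str, float]:
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([fm[name] for fm in self.fold_metrics])
            out[name] = float(np.nanmean(vals)) if not np.isnan(vals).all() else math.nan
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "fold_counts": [vars(c) for c in self.fold_counts],
                    "fold_metrics": self.fold_metrics,
                    "aggregate": self.aggregate,
                },
                fh,
                indent=1,
                default=str,
            )


def _fold_seed(seed: int, fold: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([int(seed), int(fold), int(salt)])
    return int(ss.generate_state(1)[0] % (2**31))


def _cv_on_features(
    features: FeatureMatrix,
    *,
    m: int | None,
    augmentation: AugmentationConfig | None,
    classifier: ClassifierSpec,
    folds: int,
    seed: int,
    leaky_selection: bool,
    standardize: bool,
    config_echo: dict,
) -> CVReport:
    y = features.labels
    if y is None:
        raise ValidationError("cross-validation requires labels")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"stratification error: smallest class has {counts.min()} samples "
            f"< {folds} folds"
        )
    select = (
        m is not None
        and m > 0
        and "aaindex" in set(features.blocks)
        and m < int(features.block_mask("aaindex").sum())
    )
    leaky_model = None
    if select and leaky_selection:
        logger.warning("mRMR fitted on the pooled dataset (leaky reproduction mode)")
        leaky_model = fit_mrmr(features, m)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[dict[str, float]] = []
    for fold, (tr, te) in enumerate(skf.split(features.values, y)):
        X_tr = features.subset_samples(tr)
        X_te = features.subset_samples(te)
        if select:
            model = leaky_model if leaky_selection else fit_mrmr(X_tr, m)
            X_tr = apply_selection(X_tr, model)
            X_te = apply_selection(X_te, model)
        if augmentation is not None and augmentation.n_fraction > 0:
            fold_cfg = replace(
                augmentation,
                seed=_fold_seed(seed, fold, salt=augmentation.seed or 0),
            )
            test_ids = set(X_te.sample_ids)
            X_tr = augment_training_set(X_tr, fold_cfg)
            sources = {s for s in (X_tr.provenance or ()) if s is not None}
            if sources & test_ids:  # leakage guard
                raise AcpdaError(
                    "leakage: test sample(s) used as augmentation sources: "
                    f"{sorted(sources & test_ids)[:5]}"
                )
        tr_vals, te_vals = X_tr.values, X_te.values
        if standardize:
            logger.info("per-fold standardization enabled")
            scaler = StandardScaler().fit(tr_vals)
            tr_vals = scaler.transform(tr_vals)
            te_vals = scaler.transform(te_vals)
        clf = classifier.build(_fold_seed(seed, fold, salt=1))
        clf.fit(tr_vals, X_tr.labels)
        y_pred = clf.predict(te_vals)
        c = confusion_from_predictions(X_te.labels, y_pred)
        fold_counts.append(c)
        fold_metrics.append(compute_metrics(c))

    return CVReport(config=config_echo, fold_counts=fold_counts, fold_metrics=fold_metrics)


def run_cv(
    dataset: LabeledDataset,
    *,
    l_x: int = 40,
    feature_set: Sequence[str] = ("bpf", "aaindex"),
    m: int | None = 50,
    augmentation: AugmentationConfig | None = None,
    classifier: ClassifierSpec | None = None,
    folds: int = 5,
    seed: int = 0,
    table: AAIndexTable | None = None,
    kmer_config: KmerConfig | None = None,
    leaky_selection: bool = False,
    standardize: bool = False,
) -> CVReport:
    """Stratified ``folds``-fold cross-validation of the full pipeline.

    Per fold: length-normalize, encode, fit mRMR on the training fold, apply
    to both splits, augment the training rows only, fit the classifier, and
    score the untouched test fold.  Bit-reproducible given (dataset, config,
    seed) for deterministic classifiers.
    """
    classifier = classifier or ClassifierSpec()
    table = table or default_aaindex_table()
    features = encode_dataset(
        dataset, l_x, feature_set, table=table, kmer_config=kmer_config
    )
    config_echo = {
        "l_x": l_x,
        "feature_set": list(feature_set),
        "m": m,
        "augmentation": None if augmentation is None else vars(augmentation),
        "classifier": {"kind": classifier.kind, "hyperparams": classifier.hyperparams},
        "folds": folds,
        "seed": seed,
        "leaky_selection": leaky_selection,
        "standardize": standardize,
    }
    return _cv_on_features(
        features,
        m=m,
        augmentation=augmentation,
        classifier=classifier,
        folds=folds,
        seed=seed,
        leaky_selection=leaky_selection,
        standardize=standardize,
        config_echo=config_echo,
    )


def parameter_sweep(
    dataset: LabeledDataset,
    *,
    l_x_values: Sequence[int] = (40, 50, 60),
    n_fractions: Sequence[float] = (1.0, 2.0, 3.0),
    feature_set: Sequence[str] = ("bpf", "aaindex"),
    m: int | None = 50,
    a: float = 0.005,
    classifier: ClassifierSpec | None = None,
    folds: int = 5,
    seed: int = 0,
    table: AAIndexTable | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Grid over normalized length L_X and pseudosample fraction N.

    Returns one row per (L_X, N) with the aggregate metrics and a ``best``
    flag on the maximum-MCC row (ties broken by smaller L_X, then smaller N).
    """
    classifier = classifier or ClassifierSpec()
    table = table or default_aaindex_table()
    rows = []
    for l_x in l_x_values:
        features = encode_dataset(dataset, l_x, feature_set, table=table)
        for n_frac in n_fractions:
            aug = AugmentationConfig(a=a, n_fraction=n_frac)
            report = _cv_on_features(
                features,
                m=m,
                augmentation=aug,
                classifier=classifier,
                folds=folds,
                seed=seed,
                leaky_selection=cv_kwargs.get("leaky_selection", False),
                standardize=cv_kwargs.get("standardize", False),
                config_echo={"l_x": l_x, "n_fraction": n_frac, "seed": seed},
            )
            rows.append(
                {"L_X": l_x, "N": int(round(100 * n_frac)), **report.aggregate}
            )
    df = pd.DataFrame(rows)
    # best row: max MCC, ties -> smaller L_X then smaller N
    order = df.sort_values(["MCC", "L_X", "N"], ascending=[False, True, True])
    df["best"] = False
    df.loc[order.index[0], "best"] = True
    return df


def feature_ablation(
    dataset: LabeledDataset,
    *,
    l_x: int = 40,
    m: int | None = 50,
    classifier: ClassifierSpec | None = None,
    folds: int = 5,
    seed: int = 0,
    table: AAIndexTable | None = None,
    kmer_config: KmerConfig | None = None,
) -> pd.DataFrame:
    """Evaluate the three feature blocks and all their concatenations (7
    configurations), without data augmentation, under identical folds."""
    classifier = classifier or ClassifierSpec()
    table = table or default_aaindex_table()
    full = encode_dataset(
        dataset, l_x, ("bpf", "aaindex", "kmer"), table=table, kmer_config=kmer_config
    )
    rows = []
    for fs in ALL_FEATURE_SETS:
        keep = np.array([b in fs for b in full.blocks])
        sub = FeatureMatrix(
            sample_ids=full.sample_ids,
            feature_names=tuple(np.array(full.feature_names)[keep]),
            values=full.values[:, keep],
            blocks=tuple(np.array(full.blocks)[keep]),
            labels=full.labels,
        )
        report = _cv_on_features(
            sub,
            m=m,
            augmentation=None,
            classifier=classifier,
            folds=folds,
            seed=seed,
            leaky_selection=False,
            standardize=False,
            config_echo={"feature_set": list(fs), "l_x": l_x, "seed": seed},
        )
        rows.append({"features": "+".join(fs), **report.aggregate})
    return pd.DataFrame(rows)


def classifier_comparison(
    dataset: LabeledDataset,
    *,
    kinds: Sequence[str] = CLASSIFIER_KINDS,
    l_x: int = 40,
    feature_set: Sequence[str] = ("bpf", "aaindex"),
    m: int | None = 50,
    augmentation: AugmentationConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    table: AAIndexTable | None = None,
) -> pd.DataFrame:
    """Paired MCC with and without augmentation for each classifier kind,
    under byte-identical fold assignments (same seed)."""
    augmentation = augmentation or AugmentationConfig()
    table = table or default_aaindex_table()
    features = encode_dataset(dataset, l_x, feature_set, table=table)
    rows = []
    for kind in kinds:
        spec = ClassifierSpec(kind=kind)
        out = {}
        for label, aug in (("mcc_augmented", augmentation), ("mcc_baseline", None)):
            report = _cv_on_features(
                features,
                m=m,
                augmentation=aug,
                classifier=spec,
                folds=folds,
                seed=seed,
                leaky_selection=False,
                standardize=False,
                config_echo={"classifier": kind, "augmented": aug is not None},
            )
            out[label] = report.aggregate["MCC"]
        rows.append({"classifier": kind, **out})
    return pd.DataFrame(rows)
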