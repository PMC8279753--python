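import math

import numpy as np
import pytest

from acpda import (
    AcpdaError,
    AugmentationConfig,
    ClassifierSpec,
    ConfusionCounts,
    SyntheticSpec,
    ValidationError,
    classifier_comparison,
    compute_metrics,
    feature_ablation,
    generate_dataset,
    parameter_sweep,
    run_cv,
    synthetic_aaindex_table,
)
from acpda.model_eval import confusion_from_predictions

FAST = ClassifierSpec(kind="extratrees", hyperparams={"n_estimators": 30})
SMALL_TABLE = synthetic_aaindex_table(n_indices=20, seed=1)


@pytest.fixture(scope="module")
def small_dataset():
    return generate_dataset(
        SyntheticSpec(n_pos=30, n_neg=30, length_range=(10, 30), signal_strength=1.0, seed=5)
    )


class TestComputeMetrics:
    def test_hand_computed_balanced_case(self):
        m = compute_metrics(ConfusionCounts(TP=3, TN=3, FP=1, FN=1))
        assert m == pytest.approx(
            {"ACC": 75.0, "PRE": 75.0, "SN": 75.0, "SP": 75.0, "MCC": 50.0}
        )

    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(TP=10, TN=8, FP=0, FN=0))
        assert all(v == 100.0 for v in m.values())

    def test_label_swap_symmetry(self):
        a = compute_metrics(ConfusionCounts(TP=5, TN=2, FP=3, FN=1))
        b = compute_metrics(ConfusionCounts(TP=2, TN=5, FP=1, FN=3))
        assert a["ACC"] == pytest.approx(b["ACC"])
        assert abs(a["MCC"]) == pytest.approx(abs(b["MCC"]))
        assert a["SN"] == pytest.approx(b["SP"])
        assert a["SP"] == pytest.approx(b["SN"])

    def test_zero_denominator_is_nan_not_zero(self):
        m = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=3))
        assert math.isnan(m["PRE"]) and math.isnan(m["MCC"])
        assert m["SP"] == 100.0

    def test_matches_bruteforce_counting_from_predictions(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, 60)
        y_pred = rng.integers(0, 2, 60)
        c = confusion_from_predictions(y_true, y_pred)
        # independent per-pair counting
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)
        assert c.total == 60


class TestRunCV:
    def test_planted_signal_is_learned(self, small_dataset):
        # small-sample smoke check: well above chance (the tight MCC bound
        # is asserted at full problem size elsewhere)
        report = run_cv(
            small_dataset, l_x=20, m=10, table=SMALL_TABLE,
            classifier=FAST, seed=0,
        )
        assert report.aggregate["MCC"] > 50
        assert len(report.fold_metrics) == 5

    def test_metrics_recomputable_from_stored_counts(self, small_dataset):
        report = run_cv(
            small_dataset, l_x=20, m=10, table=SMALL_TABLE, classifier=FAST, seed=0
        )
        for c, m in zip(report.fold_counts, report.fold_metrics):
            assert compute_metrics(c) == pytest.approx(m, nan_ok=True)

    def test_bit_reproducible_for_deterministic_classifier(self, small_dataset):
        kw = dict(l_x=20, m=10, table=SMALL_TABLE, classifier=FAST, seed=3,
                  augmentation=AugmentationConfig(n_fraction=1.0))
        a = run_cv(small_dataset, **kw)
        b = run_cv(small_dataset, **kw)
        assert a.fold_metrics == b.fold_metrics
        assert a.fold_counts == b.fold_counts

    def test_too_few_samples_per_class_rejected(self):
        ds = generate_dataset(SyntheticSpec(n_pos=3, n_neg=8, seed=0))
        with pytest.raises(ValidationError, match="stratification"):
            run_cv(ds, l_x=20, m=5, table=SMALL_TABLE, classifier=FAST, folds=5)

    def test_leakage_guard_fires_on_contaminated_sources(
        self, small_dataset, monkeypatch
    ):
        """If augmentation ever reports a test sample as a pseudosample
        source, the run must abort rather than report leaky metrics."""
        import acpda.model_eval as me

        real = me.augment_training_set

        def contaminated(X_train, config):
            out = real(X_train, config)
            prov = list(out.provenance)
            # claim some sample outside the training fold was a source
            missing = set(f"syn_pos_{i}" for i in range(30)) - set(X_train.sample_ids)
            prov[-1] = sorted(missing)[0]
            out.provenance = tuple(prov)
            return out

        monkeypatch.setattr(me, "augment_training_set", contaminated)
        with pytest.raises(AcpdaError, match="leakage"):
            run_cv(
                small_dataset, l_x=20, m=10, table=SMALL_TABLE, classifier=FAST,
                augmentation=AugmentationConfig(n_fraction=1.0), seed=0,
            )

    def test_report_json(self, tmp_path, small_dataset):
        report = run_cv(small_dataset, l_x=20, m=5, table=SMALL_TABLE,
                        classifier=FAST, seed=0)
        p = tmp_path / "report.json"
        report.to_json(p)
        import json

        loaded = json.loads(p.read_text())
        assert loaded["aggregate"]["MCC"] == pytest.approx(report.aggregate["MCC"])


@pytest.fixture(scope="module")
def sweep_df(small_dataset):
    return parameter_sweep(
        small_dataset, l_x_values=(15, 20), n_fractions=(0.5, 1.0),
        m=10, table=SMALL_TABLE, classifier=FAST, seed=0,
    )


class TestParameterSweep:
    def test_grid_shape(self, sweep_df):
        assert len(sweep_df) == 4
        assert set(sweep_df["L_X"]) == {15, 20}
        assert set(sweep_df["N"]) == {50, 100}

    def test_best_flag_marks_max_mcc(self, sweep_df):
        best = sweep_df[sweep_df["best"]]
        assert len(best) == 1
        assert best.iloc[0]["MCC"] == sweep_df["MCC"].max()

    def test_single_cell_degenerates_to_run_cv(self, small_dataset):
        df = parameter_sweep(
            small_dataset, l_x_values=(20,), n_fractions=(1.0,),
            m=10, table=SMALL_TABLE, classifier=FAST, seed=7,
        )
        report = run_cv(
            small_dataset, l_x=20, m=10, table=SMALL_TABLE, classifier=FAST,
            seed=7, augmentation=AugmentationConfig(a=0.005, n_fraction=1.0),
        )
        assert df.iloc[0]["MCC"] == pytest.approx(report.aggregate["MCC"])

    def test_tie_break_prefers_smaller_lx_then_n(self, small_dataset, monkeypatch):
        import acpda.model_eval as me

        # force identical metrics in every cell so the tie rule decides
        def flat_cv(features, **kwargs):
            c = me.ConfusionCounts(TP=3, TN=3, FP=1, FN=1)
            return me.CVReport(
                config={}, fold_counts=[c], fold_metrics=[me.compute_metrics(c)]
            )

        monkeypatch.setattr(me, "_cv_on_features", flat_cv)
        df = me.parameter_sweep(
            small_dataset, l_x_values=(20, 15), n_fractions=(1.0, 0.5),
            m=5, table=SMALL_TABLE, classifier=FAST,
        )
        best = df[df["best"]].iloc[0]
        assert (best["L_X"], best["N"]) == (15, 50)


class TestFeatureAblation:
    def test_seven_configurations_and_dimensions(self, small_dataset):
        df = feature_ablation(
            small_dataset, l_x=20, m=10, table=SMALL_TABLE, classifier=FAST, seed=0
        )
        assert len(df) == 7
        assert set(df["features"]) == {
            "bpf", "aaindex", "kmer", "bpf+aaindex", "bpf+kmer",
            "aaindex+kmer", "bpf+aaindex+kmer",
        }

    def test_signal_blocks_outrank_noise_only_block(self, small_dataset):
        """The planted signal is N-terminal composition: bpf and aaindex see
        it, the global kmer profile barely does."""
        df = feature_ablation(
            small_dataset, l_x=20, m=10, table=SMALL_TABLE, classifier=FAST, seed=0
        ).set_index("features")
        assert df.loc["bpf", "MCC"] > df.loc["kmer", "MCC"]
        assert df.loc["aaindex", "MCC"] > df.loc["kmer", "MCC"]


class TestClassifierComparison:
    def test_paired_output_shape(self, small_dataset):
        df = classifier_comparison(
            small_dataset, kinds=("dt", "extratrees"), l_x=20, m=10,
            table=SMALL_TABLE, seed=0,
        )
        assert list(df.columns) == ["classifier", "mcc_augmented", "mcc_baseline"]
        assert len(df) == 2

    def test_zero_fraction_augmentation_matches_baseline(self, small_dataset):
        df = classifier_comparison(
            small_dataset, kinds=("dt",), l_x=20, m=10, table=SMALL_TABLE,
            augmentation=AugmentationConfig(n_fraction=0.0), seed=0,
        )
        assert df.iloc[0]["mcc_augmented"] == pytest.approx(df.iloc[0]["mcc_baseline"])


class TestClassifierSpec:
    def test_mlp_defaults(self):
        clf = ClassifierSpec(kind="mlp").build(seed=0)
        assert clf.hidden_layer_sizes == (100,) * 6
        assert clf.alpha == 0.01
        assert clf.activation == "relu"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierSpec(kind="boosted-llama")
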