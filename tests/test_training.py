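"""Metrics, statistical comparisons and protocol structure.

Training-dependent tests here use deliberately tiny datasets and epoch
counts: they check bookkeeping (partitions, determinism, report shapes),
not classification quality.
"""

import numpy as np
import pytest

from cuffgraph.data import LABELS
from cuffgraph.geometry import CuffLayout, GraphConfig
from cuffgraph.model import ModelConfig
from cuffgraph.synthetic import SynthConfig, generate_dataset
from cuffgraph.training import (ComparisonResult, DegenerateComparisonError,
                                EvalReport, FoldResult, TrainConfig,
                                _fold_result, ablation_table, compare_runs,
                                evaluate, run_ablations, run_loso,
                                run_within_subject, sweep_graph_hparams,
                                train_model)


def tiny_model():
    return ModelConfig(encoder="lstm", encoder_units=3, edgeconv_units=3,
                       gconv_units=4, dense_units=(4,), dropout=0.0, l2=0.0)


def tiny_train(seed=0, **kw):
    defaults = dict(learning_rate=1e-2, batch_size=64, max_epochs=2,
                    patience=2, augment_fraction=0.05, seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


def tiny_dataset(n_subjects=3, n_per_class=6, seed=0):
    layout = CuffLayout(3, 4)
    return generate_dataset(layout, SynthConfig(
        n_subjects=n_subjects, n_per_class=n_per_class, seed=seed,
        n_timesamples=20, class_origins=((0, 0), (1, 1), (2, 3))))


def report_from_f1(values: dict, excluded=()) -> EvalReport:
    folds = [FoldResult(held_out=k, accuracy=v, macro_f1=v, per_class={},
                        confusion=[[1, 0, 0], [0, 1, 0], [0, 0, 1]], n_test=3)
             for k, v in values.items()]
    incl = [v for k, v in values.items() if k not in excluded]
    return EvalReport(folds=folds, mean_accuracy=float(np.mean(incl)),
                      sd_accuracy=float(np.std(incl, ddof=1)) if len(incl) > 1 else 0.0,
                      mean_macro_f1=float(np.mean(incl)),
                      sd_macro_f1=float(np.std(incl, ddof=1)) if len(incl) > 1 else 0.0,
                      validation_subjects=tuple(excluded))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        fr = _fold_result(y, y, "s")
        assert fr.accuracy == pytest.approx(100.0)
        assert fr.macro_f1 == pytest.approx(100.0)
        assert np.trace(fr.confusion) == 6

    def test_hand_computed_confusion_matrix(self):
        """Confusion [[2,0,0],[0,0,2],[0,0,2]]: accuracy 4/6, per-class F1
        {1, 0, 2/3}, macro-F1 5/9."""
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 0, 2, 2, 2, 2])
        fr = _fold_result(y_true, y_pred, "s")
        assert fr.confusion == [[2, 0, 0], [0, 0, 2], [0, 0, 2]]
        assert fr.accuracy == pytest.approx(100 * 4 / 6)
        assert fr.per_class[LABELS[0]]["f1"] == pytest.approx(1.0)
        assert fr.per_class[LABELS[1]]["f1"] == pytest.approx(0.0)
        assert fr.per_class[LABELS[2]]["f1"] == pytest.approx(2 / 3)
        assert fr.macro_f1 == pytest.approx(100 * 5 / 9)

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        y_true = np.repeat([0, 1, 2], 1000)
        y_pred = rng.integers(0, 3, size=3000)
        fr = _fold_result(y_true, y_pred, "s")
        assert 28.0 < fr.accuracy < 39.0

    def test_confusion_total_equals_test_size(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, size=57)
        y_pred = rng.integers(0, 3, size=57)
        fr = _fold_result(y_true, y_pred, "s")
        assert np.sum(fr.confusion) == fr.n_test == 57
        assert fr.accuracy == pytest.approx(
            100.0 * np.trace(fr.confusion) / 57)


class TestCompareRuns:
    def test_paired_t_statistic_known_value(self):
        """Differences [1, 2, 3]: t = mean/(sd/sqrt(n)) = 2/(1/sqrt(3)) = 2*sqrt(3)."""
        a = report_from_f1({"s1": 11.0, "s2": 22.0, "s3": 33.0})
        b = report_from_f1({"s1": 10.0, "s2": 20.0, "s3": 30.0})
        res = compare_runs(a, b, paired=True)
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.df == 2
        assert res.test_type == "paired t-test"

    def test_identical_reports_raise_degenerate_error(self):
        a = report_from_f1({"s1": 50.0, "s2": 60.0})
        b = report_from_f1({"s1": 50.0, "s2": 60.0})
        with pytest.raises(DegenerateComparisonError):
            compare_runs(a, b, paired=True)

    def test_unpaired_equal_means_not_significant(self):
        a = report_from_f1({"s1": 40.0, "s2": 60.0})
        b = report_from_f1({"s3": 60.0, "s4": 40.0})
        res = compare_runs(a, b, paired=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)
        assert not res.significant
        assert res.test_type == "Welch t-test"

    def test_matches_t_distribution_cdf(self):
        """Two-sided p equals 2 * survival function of |t| at df = n-1."""
        from scipy import stats
        a = report_from_f1({"s1": 12.0, "s2": 25.0, "s3": 31.0, "s4": 47.0})
        b = report_from_f1({"s1": 10.0, "s2": 20.0, "s3": 30.0, "s4": 40.0})
        res = compare_runs(a, b, paired=True)
        diffs = np.array([2.0, 5.0, 1.0, 7.0])
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(4))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.pvalue == pytest.approx(2 * stats.t.sf(abs(t), df=3), abs=1e-12)

    def test_validation_subjects_excluded_from_comparison(self):
        a = report_from_f1({"s1": 10.0, "s2": 20.0, "s3": 30.0, "v": 99.0},
                           excluded=("v",))
        b = report_from_f1({"s1": 9.0, "s2": 18.0, "s3": 27.0, "v": 0.0},
                           excluded=("v",))
        res = compare_runs(a, b, paired=True)
        assert res.df == 2  # v dropped


class TestTrainModel:
    def test_rejects_degenerate_training_sets(self):
        ds = tiny_dataset()
        single = ds.subset(np.flatnonzero(ds.labels == 0))
        with pytest.raises(ValueError, match="2 classes"):
            train_model(single, tiny_model(), GraphConfig(k=3), tiny_train())
        with pytest.raises(ValueError, match="empty"):
            train_model(ds.subset([]), tiny_model(), GraphConfig(k=3),
                        tiny_train())

    def test_deterministic_under_seed(self):
        ds = tiny_dataset()
        kw = dict(mcfg=tiny_model(), gcfg=GraphConfig(k=3), tcfg=tiny_train(7))
        m1 = train_model(ds, kw["mcfg"], kw["gcfg"], kw["tcfg"])
        m2 = train_model(ds, kw["mcfg"], kw["gcfg"], kw["tcfg"])
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data), k
        assert m1.history == m2.history

    def test_history_is_finite_and_best_checkpoint_restored(self):
        ds = tiny_dataset()
        model = train_model(ds, tiny_model(), GraphConfig(k=3),
                            tiny_train(max_epochs=4, patience=4))
        losses = [h["val_loss"] for h in model.history]
        assert np.isfinite(losses).all()
        assert np.isfinite([h["train_loss"] for h in model.history]).all()

    def test_normalization_uses_training_statistics(self):
        ds = tiny_dataset()
        model = train_model(ds, tiny_model(), GraphConfig(k=3), tiny_train())
        x = ds.values.astype(np.float32)
        assert np.allclose(model.channel_mean, x.mean(axis=(0, 2)), atol=1e-5)
        normed = model.normalize(x)
        assert abs(normed.mean()) < 0.1


class TestLearning:
    def test_overfits_clean_separable_data(self):
        """On a small low-noise dataset with strong class structure, the
        classifier must fit its own training set well above chance."""
        from cuffgraph.model import ModelConfig
        from cuffgraph.training import evaluate
        layout = CuffLayout(7, 8)
        ds = generate_dataset(layout, SynthConfig(
            n_subjects=2, n_per_class=15, noise_sd=0.05,
            subject_gain_sd=0.0, subject_jitter_sd=0.0, seed=11))
        mcfg = ModelConfig(encoder="lstm", encoder_units=8, edgeconv_units=8,
                           gconv_units=16, dense_units=(16,), dropout=0.0,
                           l2=0.0, node_feature="mean")
        tcfg = TrainConfig(learning_rate=1e-2, batch_size=48, max_epochs=120,
                           patience=120, augment_fraction=0.0, seed=2)
        model = train_model(ds, mcfg, GraphConfig(k=5, sigma=2.0), tcfg)
        fr = evaluate(model, ds)
        assert fr.accuracy > 90.0, f"train-set accuracy only {fr.accuracy:.1f}%"


class TestProtocols:
    def test_loso_folds_partition_subjects(self):
        ds = tiny_dataset(n_subjects=3)
        report = run_loso(ds, tiny_model(), GraphConfig(k=3), tiny_train())
        assert sorted(f.held_out for f in report.folds) == ds.subject_ids
        assert sum(f.n_test for f in report.folds) == len(ds)
        assert 0.0 <= report.mean_macro_f1 <= 100.0
        assert report.protocol == "loso"
        assert report.provenance["versions"]["numpy"]

    def test_loso_excludes_validation_subjects_from_aggregate(self):
        ds = tiny_dataset(n_subjects=3)
        rep = run_loso(ds, tiny_model(), GraphConfig(k=3),
                       tiny_train(validation_subjects=("S01",)))
        incl = [f.macro_f1 for f in rep.folds if f.held_out != "S01"]
        assert rep.mean_macro_f1 == pytest.approx(np.mean(incl))
        assert len(rep.folds) == 3  # still evaluated and reported

    def test_loso_all_subjects_excluded_raises(self):
        ds = tiny_dataset(n_subjects=2)
        with pytest.raises(ValueError, match="no folds"):
            run_loso(ds, tiny_model(), GraphConfig(k=3),
                     tiny_train(validation_subjects=("S01", "S02")))

    def test_within_subject_aggregates_fold_means(self):
        ds = tiny_dataset(n_subjects=2, n_per_class=6)
        rep = run_within_subject(ds, tiny_model(), GraphConfig(k=3),
                                 tiny_train(), n_folds=3)
        assert sorted(f.held_out for f in rep.folds) == ds.subject_ids
        for f in rep.folds:
            assert f.n_test == 18  # all of the subject's signatures, once each
        assert rep.protocol == "within_subject"

    def test_report_json_roundtrip(self, tmp_path):
        ds = tiny_dataset(n_subjects=2)
        rep = run_loso(ds, tiny_model(), GraphConfig(k=3), tiny_train())
        path = tmp_path / "rep.json"
        rep.to_json(path)
        back = EvalReport.from_json(path)
        assert back.mean_macro_f1 == pytest.approx(rep.mean_macro_f1)
        assert [f.held_out for f in back.folds] == [f.held_out for f in rep.folds]

    def test_sweep_grid_shape_and_argmax(self):
        ds = tiny_dataset(n_subjects=2)
        table, best = sweep_graph_hparams(ds, tiny_model(), tiny_train(),
                                          k_grid=[2, 3], sigma_grid=[1.0, 2.0])
        assert table.shape == (2, 2)
        assert table.notna().all().all()
        assert ((table >= 0) & (table <= 100)).all().all()
        k, sigma = best
        assert table.loc[sigma, k] == table.max().max()

    def test_ablations_share_settings_and_differ_one_factor(self):
        ds = tiny_dataset(n_subjects=2)
        reports = run_ablations(ds, tiny_model(), GraphConfig(k=3, sigma=2.0),
                                tiny_train(),
                                variants=("geodesic", "cnn1d", "random"))
        assert set(reports) == {"geodesic", "cnn1d", "random"}
        table = ablation_table(reports)
        assert len(table) == 3
        assert "mean_macro_f1" in table.columns
        geo = reports["geodesic"].provenance["config"]
        cnn = reports["cnn1d"].provenance["config"]
        assert geo["graph"] == cnn["graph"]  # identical graph settings
        assert cnn["model"]["encoder"] == "cnn1d"
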