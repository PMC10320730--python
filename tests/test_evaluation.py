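import numpy as np
import pytest

from saelgmda.autoencoder import SAEConfig
from saelgmda.classifier import ClassifierConfig
from saelgmda.evaluation import (
    CvPlan,
    _mask_training_matrix,
    compute_metrics,
    make_folds,
    matthews_corrcoef,
    run_cv,
)
from saelgmda.io_formats import AssociationMatrix
from saelgmda.synthetic import FixtureSpec, generate_fixture
from helpers import brute_force_auc


@pytest.fixture(scope="module")
def fixture_10x20():
    return generate_fixture(
        FixtureSpec(
            n_diseases=10, n_microbes=20, n_blocks=4,
            within_block_density=0.6, background_density=0.04,
            genes_per_disease=6, block_pool_genes=12, seed=11,
        )
    )


class TestMakeFolds:
    def test_cv1_divides_diseases_evenly(self, fixture_10x20):
        folds = make_folds(fixture_10x20.X, CvPlan(mode="CV1", k=5, seed=1))
        assert [len(f) for f in folds] == [2, 2, 2, 2, 2]

    def test_cv3_covers_all_pairs(self):
        X = AssociationMatrix(
            np.eye(3, 4, dtype=np.int8), ("d1", "d2", "d3"),
            ("m1", "m2", "m3", "m4"),
        )
        folds = make_folds(X, CvPlan(mode="CV3", k=4, seed=0))
        assert [len(f) for f in folds] == [3, 3, 3, 3]

    @pytest.mark.parametrize("mode", ["CV1", "CV2", "CV3"])
    def test_folds_partition_exhaustively_and_disjointly(self, fixture_10x20, mode):
        X = fixture_10x20.X
        n = {"CV1": 10, "CV2": 20, "CV3": 200}[mode]
        for rep in range(3):
            folds = make_folds(X, CvPlan(mode=mode, k=5, seed=3), repetition=rep)
            concatenated = np.concatenate(folds)
            assert len(concatenated) == n
            assert set(concatenated.tolist()) == set(range(n))

    def test_too_few_entities_is_an_error(self, fixture_10x20):
        with pytest.raises(ValueError, match="at least"):
            make_folds(fixture_10x20.X, CvPlan(mode="CV1", k=11))


class TestMaskTrainingMatrix:
    def test_cv1_zeroes_held_out_disease_rows(self, fixture_10x20):
        X = fixture_10x20.X
        test_idx = np.array([1, 4, 7])
        masked = _mask_training_matrix(X, "CV1", test_idx)
        assert masked.values[test_idx].sum() == 0
        keep = np.setdiff1d(np.arange(10), test_idx)
        np.testing.assert_array_equal(masked.values[keep], X.values[keep])

    def test_cv3_zeroes_only_held_out_entries(self, fixture_10x20):
        X = fixture_10x20.X
        test_idx = np.arange(0, 200, 7)
        masked = _mask_training_matrix(X, "CV3", test_idx)
        m, d = np.divmod(test_idx, 10)
        assert masked.values[d, m].sum() == 0
        assert masked.values.sum() == X.values.sum() - X.values[d, m].sum()


class TestComputeMetrics:
    def test_perfect_predictor_scores_one_everywhere(self):
        out = compute_metrics(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])
        )
        assert out == {"accuracy": 1.0, "mcc": 1.0, "auc": 1.0, "aupr": 1.0}

    def test_perfectly_wrong_predictor_has_auc_zero(self):
        out = compute_metrics(np.array([0.9, 0.2]), np.array([0, 1]))
        assert out["auc"] == 0.0

    def test_constant_scores_give_auc_half_by_tie_convention(self):
        out = compute_metrics(np.zeros(6), np.array([1, 0, 0, 1, 0, 0]))
        assert out["auc"] == 0.5

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(30), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            out = compute_metrics(scores, labels)
            assert out["auc"] == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_mcc_confusion_and_covariance_forms_agree(self, rng):
        for _ in range(20):
            scores = rng.random(50)
            labels = rng.integers(0, 2, size=50)
            pred = (scores > 0.5).astype(int)
            tp = int(np.sum(pred & labels))
            tn = int(np.sum((1 - pred) & (1 - labels)))
            fp = int(np.sum(pred & (1 - labels)))
            fn = int(np.sum((1 - pred) & labels))
            table_form = matthews_corrcoef(tp, tn, fp, fn)
            # covariance form: cov(pred, labels) / (std * std)
            if pred.std() == 0 or labels.std() == 0:
                cov_form = 0.0
            else:
                cov_form = np.cov(pred, labels, bias=True)[0, 1] / (
                    pred.std() * labels.std()
                )
            assert table_form == pytest.approx(cov_form, abs=1e-12)


@pytest.fixture(scope="module")
def small_sae():
    return SAEConfig(layer_sizes=(30, 16, 8), epochs=8, seed=0)


class TestRunCv:
    def test_report_has_k_times_reps_fold_records(self, fixture_10x20, small_sae):
        plan = CvPlan(mode="CV3", k=4, repetitions=2, seed=5)
        report = run_cv(
            fixture_10x20.X, plan,
            disease_gene_map=fixture_10x20.disease_gene_map,
            gene_net=fixture_10x20.gene_network,
            sae_cfg=small_sae,
            clf_cfg=ClassifierConfig(n_estimators=20),
        )
        assert len(report.fold_records) == 8
        agg = report.aggregate()
        for metric in ("accuracy", "mcc", "auc", "aupr"):
            assert agg[metric]["n_folds"] + agg[metric]["n_undefined"] == 8

    def test_metric_ranges_and_scope_recorded(self, fixture_10x20, small_sae):
        plan = CvPlan(mode="CV2", k=4, repetitions=1, seed=2)
        report = run_cv(
            fixture_10x20.X, plan,
            sae_cfg=small_sae, clf_cfg=ClassifierConfig(n_estimators=20),
        )
        assert report.similarity_scope == "masked"
        for rec in report.fold_records:
            assert 0 <= rec["accuracy"] <= 1
            assert -1 <= rec["mcc"] <= 1
            if not np.isnan(rec["auc"]):
                assert 0 <= rec["auc"] <= 1 and 0 <= rec["aupr"] <= 1

    def test_single_class_test_fold_recorded_as_undefined(self):
        values = np.zeros((4, 6), dtype=np.int8)
        values[0, :3] = 1
        values[1, 3] = 1  # two diseases carry every positive
        X = AssociationMatrix(
            values, tuple(f"d{i}" for i in range(4)),
            tuple(f"m{j}" for j in range(6)),
        )
        plan = CvPlan(mode="CV1", k=4, repetitions=1, seed=0)
        with pytest.warns(UserWarning, match="single-class test fold"):
            report = run_cv(
                X, plan,
                sae_cfg=SAEConfig(layer_sizes=(10, 4), epochs=3),
                clf_cfg=ClassifierConfig(n_estimators=5, min_data_in_leaf=2),
            )
        aucs = [r["auc"] for r in report.fold_records]
        assert any(np.isnan(a) for a in aucs)
        assert report.aggregate()["auc"]["n_undefined"] >= 1

    def test_logistic_baseline_pipeline_runs(self, fixture_10x20):
        plan = CvPlan(mode="CV3", k=3, repetitions=1, seed=1)
        report = run_cv(
            fixture_10x20.X, plan, pipeline="raw_logistic",
        )
        assert len(report.fold_records) == 3
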