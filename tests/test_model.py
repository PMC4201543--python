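"""Evaluation metrics (against sklearn oracles) and classifier behavior."""

import numpy as np
import pytest

from caspcleave.dataset import TrainingSet
from caspcleave.model import (
    CleavageModel,
    ModelConfig,
    ModelError,
    auc_from_scores,
    compute_metrics,
    load_model,
)


def expand_confusion(tp, fn, fp, tn):
    """Reconstruct label/prediction vectors for the sklearn oracle."""
    y_true = [1] * (tp + fn) + [0] * (fp + tn)
    y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    return y_true, y_pred


class TestComputeMetrics:
    def test_published_holdout_counts(self):
        """The optimized forest's hold-out confusion counts reproduce the
        printed accuracy, kappa and MCC."""
        rep = compute_metrics(191, 6, 5, 788)
        assert rep.acc_percent == pytest.approx(98.89, abs=0.005)
        assert rep.kappa == pytest.approx(0.97, abs=0.005)
        assert rep.mcc == pytest.approx(0.97, abs=0.005)
        assert rep.prc_percent == pytest.approx(97.0, abs=0.5)
        assert rep.spc_percent == pytest.approx(99.0, abs=0.5)

    def test_combined_set_counts(self):
        rep = compute_metrics(644, 16, 24, 2614)
        assert rep.acc_percent == pytest.approx(98.79, abs=0.005)

    def test_perfect_classifier(self):
        rep = compute_metrics(50, 0, 0, 200)
        assert rep.kappa == pytest.approx(1.0)
        assert rep.mcc == pytest.approx(1.0)
        assert rep.acc_percent == pytest.approx(100.0)

    def test_kappa_mcc_one_iff_no_errors(self):
        rep = compute_metrics(50, 1, 0, 200)
        assert rep.kappa < 1.0 and rep.mcc < 1.0

    def test_division_by_zero_reported_as_undefined(self):
        rep = compute_metrics(0, 10, 0, 90)  # no positive predictions
        assert rep.prc_percent is None
        assert rep.mcc is None
        assert rep.acc_percent == pytest.approx(90.0)

    def test_cost_is_weighted_error_count(self):
        rep = compute_metrics(10, 3, 7, 80, cost_fp=2.0, cost_fn=5.0)
        assert rep.cost == pytest.approx(2.0 * 7 + 5.0 * 3)

    def test_agrees_with_sklearn_on_random_confusion_matrices(self):
        """Closed forms match the independent oracle to 1e-12 (1000 draws)."""
        from sklearn.metrics import (
            accuracy_score,
            cohen_kappa_score,
            matthews_corrcoef,
        )

        rng = np.random.default_rng(1234)
        for _ in range(1000):
            tp, fn, fp, tn = rng.integers(1, 200, size=4)
            rep = compute_metrics(int(tp), int(fn), int(fp), int(tn))
            y_true, y_pred = expand_confusion(tp, fn, fp, tn)
            assert rep.acc_percent == pytest.approx(
                100.0 * accuracy_score(y_true, y_pred), abs=1e-12
            )
            assert rep.kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12
            )
            assert rep.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_auc_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(50):
            y = rng.integers(0, 2, size=60)
            if y.sum() in (0, 60):
                continue
            s = np.round(rng.random(60), 1)  # coarse scores force ties
            paired = list(zip(s.tolist(), y.tolist()))
            assert auc_from_scores(paired) == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ModelError):
            compute_metrics(0, 0, 0, 0)


class TestCleavageModel:
    def test_single_class_training_set_rejected(self, tiny_training_set):
        ts = TrainingSet(tiny_training_set.positives, [], tiny_training_set.provenance)
        with pytest.raises(ModelError, match="both classes"):
            CleavageModel(ts, {}, ModelConfig(n_trees=10))

    def test_separable_synthetic_data_gives_high_training_auc(self, small_model, ratio_fixture):
        from caspcleave.dataset import build_training_set

        ts = build_training_set(list(ratio_fixture.records), list(ratio_fixture.annotations))
        rep = small_model.evaluate(
            ts, {a.protein_id: a for a in map_structures(ratio_fixture)}
        )
        assert rep.auc > 0.95

    def test_same_seed_gives_identical_out_of_fold_scores(self, ratio_fixture):
        from caspcleave.dataset import build_training_set

        records = list(ratio_fixture.records)
        ts = build_training_set(records, list(ratio_fixture.annotations))
        cfg = ModelConfig(n_trees=50, seed=5, folds=5)
        r1 = CleavageModel.from_training_data(records, ts, cfg).cross_validate()
        r2 = CleavageModel.from_training_data(records, ts, cfg).cross_validate()
        assert r1.to_dict() == r2.to_dict()

    def test_label_shuffled_data_scores_at_chance(self, ratio_fixture):
        """Kappa ~ 0 and AUC ~ 0.5 when labels carry no information."""
        from caspcleave.synth import build_decoy_training_set

        records = list(ratio_fixture.records)
        anns = list(ratio_fixture.annotations)
        ts = build_decoy_training_set(records, anns, 3 * len(anns), seed=9)
        # shuffle: relabel by swapping half the positives with negatives
        rng = np.random.default_rng(9)
        wins = ts.windows()
        labels = ts.labels()
        perm = rng.permutation(len(wins))
        k = ts.n_positive
        shuffled_pos = [wins[i] for i in perm[:k]]
        shuffled_neg = [wins[i] for i in perm[k:]]
        ts2 = TrainingSet(shuffled_pos, shuffled_neg, ts.provenance)
        cfg = ModelConfig(n_trees=100, seed=5, folds=5)
        rep = CleavageModel.from_training_data(records, ts2, cfg).cross_validate()
        assert abs(rep.kappa) < 0.1
        assert abs(rep.auc - 0.5) < 0.07

    def test_folds_larger_than_class_rejected(self, tiny_training_set):
        from caspcleave.pwm import BackgroundDistribution

        cfg = ModelConfig(n_trees=10, folds=200)
        m = CleavageModel(
            tiny_training_set, {}, cfg, background=BackgroundDistribution.uniform()
        )
        with pytest.raises(ModelError, match="folds"):
            m.cross_validate()

    def test_summary_mentions_configuration(self, small_model):
        text = small_model.summary()
        assert "random_forest" in text
        assert "150" in text  # tree count


def map_structures(fixture):
    from caspcleave.structure import predict_structure_baseline

    return [predict_structure_baseline(r) for r in fixture.records]


class TestPersistence:
    def test_save_load_scores_bitwise_identical(self, small_model, ratio_fixture, tmp_path):
        from caspcleave.seqio import extract_window

        p = tmp_path / "model.joblib"
        small_model.save(p)
        back = load_model(p)
        rec = ratio_fixture.records[0]
        probes = [
            extract_window(rec, pos)
            for pos in range(5, len(rec) - 4, max(1, len(rec) // 10))
        ][:10]
        for w in probes:
            assert back.score_window(w) == small_model.score_window(w)

    def test_model_file_records_pwm_metadata(self, small_model, tmp_path):
        p = tmp_path / "model.joblib"
        small_model.save(p)
        back = load_model(p)
        assert back.pwm.n_sequences == small_model.pwm.n_sequences
        assert back.pwm.pseudocount == small_model.pwm.pseudocount
        assert np.array_equal(back.pwm.log2_ratio, small_model.pwm.log2_ratio)

    def test_corrupt_file_raises(self, tmp_path):
        p = tmp_path / "junk.joblib"
        p.write_bytes(b"not a model at all")
        with pytest.raises(ModelError):
            load_model(p)

    def test_version_mismatch_named(self, small_model, tmp_path, monkeypatch):
        import joblib

        p = tmp_path / "model.joblib"
        small_model.save(p)
        payload = joblib.load(p)
        payload["format_version"] = 999
        joblib.dump(payload, p)
        with pytest.raises(ModelError, match="999"):
            load_model(p)
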