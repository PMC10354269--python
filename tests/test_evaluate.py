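"""Metrics, fusion-head contracts and the evaluation protocols (with a
lightweight stub encoder so protocol logic is tested without training)."""

import numpy as np
import pytest

from motionssl.evaluate import (EvalReport, FusionClassifier, FusionHeadConfig,
                                ProtocolConfig, _report, embed_2d,
                                linear_evaluate, normalized_confusion,
                                semi_supervised_protocol, t_ci_halfwidth,
                                zero_shot_protocol)
from motionssl.synthetic import LabeledSample

rng = np.random.default_rng(99)


def _toy_samples(n=60, k=3, d=6, spread=3.0, seed=0):
    """Labelled samples whose 'skeleton'/'imu' are informative by
    construction (class mean + noise)."""
    r = np.random.default_rng(seed)
    out = []
    means = r.normal(scale=spread, size=(k, d))
    for i in range(n):
        label = i % k
        vec = means[label] + r.normal(size=d)
        skel = np.tile(vec.reshape(1, 1, d), (2, 4, 1))
        imu = np.tile(vec.reshape(1, d), (4, 1))
        out.append(LabeledSample(skeleton=skel, imu=imu, label=label,
                                 subject=1 + i % 4))
    return out


def _mean_features(samples):
    return np.stack([s.skeleton.mean(axis=(0, 1)) for s in samples])


class TestNormalizedConfusion:
    def test_perfect_predictions_give_identity(self):
        y = np.array([0, 1, 2, 1, 0])
        np.testing.assert_array_equal(normalized_confusion(y, y, 3), np.eye(3))

    def test_hand_counted_example(self):
        got = normalized_confusion([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_allclose(got, [[0.5, 0.5], [0.0, 1.0]])

    def test_matches_double_loop_tally_oracle(self):
        y = rng.integers(0, 4, size=200)
        p = rng.integers(0, 4, size=200)
        got = normalized_confusion(y, p, 4)
        ref = np.zeros((4, 4))
        for a, b in zip(y, p):
            ref[a, b] += 1
        ref = ref / ref.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(got, ref)

    def test_empty_rows_stay_zero(self):
        got = normalized_confusion([0, 0], [0, 1], 3)
        np.testing.assert_array_equal(got[2], 0.0)

    def test_out_of_range_class_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            normalized_confusion([0, 5], [0, 1], 3)


class TestReportMetrics:
    def test_perfect_predictions_score_one(self):
        rep = _report([0, 1, 2, 0], [0, 1, 2, 0], 3, [])
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0

    def test_constant_predictor_on_balanced_classes_is_chance(self):
        y = [0, 1, 2, 0, 1, 2]
        rep = _report(y, [0] * 6, 3, [])
        assert rep.accuracy == pytest.approx(1 / 3)

    def test_macro_f1_matches_hand_computed_contingency(self):
        # labels [1,0,0,0,1,1], preds [1,1,0,0,0,1]:
        # class 0: TP=2 FP=1 FN=1 -> F1 = 2/3; class 1: TP=2 FP=1 FN=1 -> 2/3
        rep = _report([1, 0, 0, 0, 1, 1], [1, 1, 0, 0, 0, 1], 2, [])
        assert rep.macro_f1 == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(4 / 6)

    def test_macro_f1_invariant_to_class_relabeling(self):
        y = rng.integers(0, 3, size=50)
        p = rng.integers(0, 3, size=50)
        perm = np.array([2, 0, 1])
        rep = _report(y, p, 3, [])
        rep_perm = _report(perm[y], perm[p], 3, [])
        assert rep.macro_f1 == pytest.approx(rep_perm.macro_f1)

    def test_per_class_recall_matches_confusion_diagonal(self):
        y = rng.integers(0, 3, size=60)
        p = rng.integers(0, 3, size=60)
        rep = _report(y, p, 3, [])
        np.testing.assert_allclose(rep.per_class_recall, np.diag(rep.confusion))


class TestFusionClassifier:
    def test_head_input_width_per_modality_count(self):
        samples = _toy_samples()
        cfg = FusionHeadConfig(per_modality_dim=16, epochs=2)
        uni = FusionClassifier({"skeleton": _mean_features}, cfg).fit(samples)
        assert uni.head_.classifier.weight.shape[0] == 16
        multi = FusionClassifier({"skeleton": _mean_features,
                                  "imu": _mean_features}, cfg).fit(samples)
        assert multi.head_.classifier.weight.shape[0] == 32

    def test_probabilities_sum_to_one(self):
        samples = _toy_samples()
        clf = FusionClassifier({"skeleton": _mean_features},
                               FusionHeadConfig(epochs=5)).fit(samples)
        np.testing.assert_allclose(clf.predict_proba(samples).sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_learns_separable_toy_problem(self):
        samples = _toy_samples(spread=4.0)
        clf = FusionClassifier({"skeleton": _mean_features},
                               FusionHeadConfig(epochs=50)).fit(samples)
        assert clf.score(samples) > 0.9

    def test_frozen_encoder_weights_unchanged_by_head_fit(self, tiny_split):
        from motionssl.pretrain import VICRegPretrainer

        from conftest import TINY_IMU, TINY_PROJECTOR, TINY_SKELETON

        train, test = tiny_split
        est = VICRegPretrainer(imu_config=TINY_IMU, skeleton_config=TINY_SKELETON,
                               projector_config=TINY_PROJECTOR, epochs=1,
                               batch_size=8, seed=0).fit(train)
        before = {k: v.copy() for k, v in est.skeleton_encoder_.state_dict().items()}
        linear_evaluate({"skeleton": est.encode_skeleton, "imu": est.encode_imu},
                        train, test, FusionHeadConfig(epochs=2))
        after = est.skeleton_encoder_.state_dict()
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k])


class TestLinearEvaluate:
    def test_report_on_separable_features(self):
        samples = _toy_samples(n=90, spread=4.0)
        train, test = samples[:60], samples[60:]
        rep = linear_evaluate({"skeleton": _mean_features}, train, test,
                              FusionHeadConfig(epochs=50))
        assert isinstance(rep, EvalReport)
        assert rep.accuracy > 0.9
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 1.0, atol=1e-12)

    def test_missing_training_class_is_warned(self):
        samples = _toy_samples(n=90)
        train = [s for s in samples[:60] if s.label != 2]
        rep = linear_evaluate({"skeleton": _mean_features}, train, samples[60:],
                              FusionHeadConfig(epochs=2))
        assert any("absent" in w for w in rep.warnings)


class TestSemiSupervised:
    def test_full_fraction_single_repeat_equals_linear_evaluation(self):
        samples = _toy_samples(n=90)
        train, test = samples[:60], samples[60:]
        hc = FusionHeadConfig(epochs=10)
        cfg = ProtocolConfig(label_fractions=(1.0,), repeats=1,
                             finetune_epochs=10, seed=0)
        table = semi_supervised_protocol({"skeleton": _mean_features}, train, test,
                                         cfg, hc)
        rep = linear_evaluate({"skeleton": _mean_features}, train, test, hc)
        assert table.loc[0, "mean_accuracy"] == pytest.approx(rep.accuracy)
        assert table.loc[0, "mean_macro_f1"] == pytest.approx(rep.macro_f1)

    def test_each_row_aggregates_the_requested_repeats(self):
        samples = _toy_samples(n=90)
        cfg = ProtocolConfig(label_fractions=(0.1, 0.5), repeats=3,
                             finetune_epochs=3, seed=1)
        table = semi_supervised_protocol({"skeleton": _mean_features},
                                         samples[:60], samples[60:], cfg)
        assert list(table.repeats) == [3, 3]
        assert list(table.p) == [0.1, 0.5]

    def test_stratified_sampling_floors_every_class_at_one(self):
        from motionssl.evaluate import _stratified_fraction

        labels = np.array([0] * 50 + [1] * 3)
        idx, floored = _stratified_fraction(labels, 0.01, np.random.default_rng(0))
        assert 1 in floored
        assert (labels[idx] == 1).sum() == 1
        assert (labels[idx] == 0).sum() == 1  # round(0.5) -> 0 -> floored


class TestZeroShot:
    class StubPretrainer:
        """Records what it was fitted on; features are class-informative."""

        def __init__(self):
            self.seen = None

        def fit(self, X):
            self.seen = list(X)
            return self

        def encode_skeleton(self, X):
            return _mean_features(X)

        def encode_imu(self, X):
            return _mean_features(X)

    def test_hidden_classes_never_enter_pretraining(self):
        samples = _toy_samples(n=90, spread=4.0)
        stub = self.StubPretrainer()
        report, recall = zero_shot_protocol(samples[:60], samples[60:], [2], stub,
                                            FusionHeadConfig(epochs=20))
        assert all(s.label != 1 for s in stub.seen)  # 1-based id 2 -> label 1
        assert set(recall) == {2}
        assert report.num_classes == 3

    def test_hiding_every_class_raises(self):
        samples = _toy_samples(n=30)
        with pytest.raises(ValueError, match="cannot cover"):
            zero_shot_protocol(samples, samples, [1, 2, 3], self.StubPretrainer())

    def test_unknown_hidden_class_raises(self):
        samples = _toy_samples(n=30)
        with pytest.raises(ValueError, match="observed"):
            zero_shot_protocol(samples, samples, [9], self.StubPretrainer())


class TestCIs:
    def test_halfwidth_shrinks_with_more_repeats(self):
        r = np.random.default_rng(3)
        pop = r.normal(loc=0.8, scale=0.05, size=1000)
        w10 = t_ci_halfwidth(pop[:10])
        w40 = t_ci_halfwidth(pop[:40])
        assert w40 < w10

    def test_single_value_has_undefined_interval(self):
        assert np.isnan(t_ci_halfwidth(np.array([0.5])))


class TestEmbed2D:
    def test_shape_and_reproducibility(self):
        X = rng.normal(size=(30, 8))
        a = embed_2d(X, seed=1)
        b = embed_2d(X, seed=1)
        assert a.shape == (30, 2)
        np.testing.assert_array_equal(a, b)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least 5"):
            embed_2d(rng.normal(size=(4, 3)))

    def test_separated_clusters_stay_separated_in_2d(self):
        from sklearn.metrics import silhouette_score

        X = np.concatenate([rng.normal(0, 1, size=(20, 5)),
                            rng.normal(8, 1, size=(20, 5))])
        labels = np.array([0] * 20 + [1] * 20)
        coords = embed_2d(X, seed=0)
        assert silhouette_score(coords, labels) > 0
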