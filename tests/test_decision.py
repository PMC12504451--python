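import numpy as np
import pytest

from slecg.decision import predict_sample, sweep_threshold, vote
from slecg.model2d import ModelConfig
from slecg.synthetic import SynthConfig, synth_record
from slecg.harmonize import harmonize_signal


class ColumnMeanModel:
    """Stand-in scorer with the NetworkHandle prediction interface: the
    score is the fraction of lit pixels, so structurally different
    segments get different, deterministic scores."""

    def __init__(self, scale=1.0):
        self.config = ModelConfig()
        self.scale = scale

    def forward(self, x, train=False):
        return np.clip(x.reshape(x.shape[0], -1).mean(axis=1) * self.scale, 0, 1)


def _brute_force_vote(labels, confidences):
    s = {"norm": 0.0, "afib": 0.0}
    for lab, c in zip(labels, confidences):
        s[lab] += c
    return "norm" if s["norm"] > s["afib"] else "afib"


class TestVote:
    @pytest.mark.parametrize("labels,conf,expected", [
        (["norm", "norm", "afib"], [0.9, 0.8, 0.7], "norm"),   # 1.7 > 0.7
        (["afib", "norm", "norm"], [0.99, 0.40, 0.50], "afib"),  # minority wins
        (["norm", "norm", "norm"], [0.1, 0.2, 0.3], "norm"),
        (["afib"], [0.5], "afib"),
        (["norm", "afib"], [0.5, 0.5], "afib"),                 # tie -> afib
    ])
    def test_examples(self, labels, conf, expected):
        assert vote(labels, conf) == expected

    def test_matches_exhaustive_oracle(self, rng):
        """All 2^3 label assignments x random confidences, >=1000 cases."""
        cases = 0
        for _ in range(150):
            for bits in range(8):
                labels = [("norm" if (bits >> k) & 1 else "afib")
                          for k in range(3)]
                conf = rng.random(3)
                assert vote(labels, conf) == _brute_force_vote(labels, conf)
                cases += 1
        assert cases >= 1000

    def test_permutation_invariance(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 6))
            labels = [("norm", "afib")[i] for i in rng.integers(0, 2, k)]
            conf = rng.random(k)
            perm = rng.permutation(k)
            assert vote(labels, conf) == vote([labels[i] for i in perm],
                                              conf[perm])

    def test_raising_afib_confidence_never_flips_to_norm(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            labels = [("norm", "afib")[i] for i in rng.integers(0, 2, k)]
            if "afib" not in labels:
                labels[0] = "afib"
            conf = rng.random(k)
            if vote(labels, conf) != "afib":
                continue
            j = labels.index("afib")
            boosted = conf.copy()
            boosted[j] = min(1.0, conf[j] + rng.random() * (1 - conf[j]))
            assert vote(labels, boosted) == "afib"

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            vote([], [])
        with pytest.raises(ValueError):
            vote(["norm"], [0.5, 0.5])
        with pytest.raises(ValueError):
            vote(["norm"], [1.5])


class TestSweep:
    def test_brute_force_example(self):
        scores = [0.9, 0.6, 0.55, 0.1]
        truth = ["norm", "norm", "afib", "afib"]
        grid = np.round(np.arange(0.05, 0.951, 0.05), 2)
        best, acc = sweep_threshold(scores, truth, grid)
        assert best == pytest.approx(0.60)
        assert acc[np.where(grid == 0.60)][0] == 1.0
        # reported accuracy matches direct recomputation at the optimum
        direct = np.mean([(s >= best) == (t == "norm")
                          for s, t in zip(scores, truth)])
        assert acc.max() == direct

    def test_separated_around_half(self):
        best, _ = sweep_threshold([0.9, 0.8, 0.2, 0.1],
                                  ["norm", "norm", "afib", "afib"],
                                  np.arange(0.1, 0.91, 0.1))
        assert best == pytest.approx(0.5)

    def test_all_identical_scores_tie_break_to_half(self):
        best, acc = sweep_threshold([0.7] * 6, ["norm"] * 3 + ["afib"] * 3,
                                    np.round(np.arange(0.05, 0.951, 0.05), 2))
        assert best == pytest.approx(0.50)
        assert np.allclose(acc, 0.5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold([0.5], ["norm"], np.array([]))


class TestPredictSample:
    def test_thirty_second_record_gives_three_segments(self):
        record, _ = synth_record(SynthConfig(
            seed=21, duration_s=30, fs=300, lead="SL"))
        sig = harmonize_signal(record.signals[0])
        result = predict_sample(ColumnMeanModel(), sig)
        assert len(result.segment_predictions.labels) == 3
        assert result.final_label in ("norm", "afib")
        assert result.s_norm + result.s_afib == pytest.approx(
            result.segment_predictions.confidences.sum())

    def test_single_segment_vote_is_that_segment(self):
        record, _ = synth_record(SynthConfig(seed=22, duration_s=10))
        sig = harmonize_signal(record.signals[0])
        result = predict_sample(ColumnMeanModel(scale=5.0), sig, threshold=0.5)
        preds = result.segment_predictions
        assert len(preds.labels) == 1
        assert result.final_label == preds.labels[0]

    def test_confidence_mapping_and_threshold_rule(self):
        record, _ = synth_record(SynthConfig(seed=23, duration_s=30, fs=300))
        sig = harmonize_signal(record.signals[0])
        result = predict_sample(ColumnMeanModel(), sig, threshold=0.15)
        preds = result.segment_predictions
        for lab, conf, raw in zip(preds.labels, preds.confidences,
                                  preds.raw_scores):
            assert lab == ("norm" if raw >= 0.15 else "afib")
            assert conf == pytest.approx(raw if lab == "norm" else 1 - raw)

    def test_polarity_inverted_record_same_outcome(self):
        record, _ = synth_record(SynthConfig(
            seed=24, duration_s=30, fs=300, lead="SL"))
        sig = record.signals[0]
        up = predict_sample(ColumnMeanModel(), harmonize_signal(sig))
        down = predict_sample(ColumnMeanModel(),
                              harmonize_signal(sig.with_samples(-sig.samples)))
        assert up.final_label == down.final_label
        np.testing.assert_allclose(up.segment_predictions.raw_scores,
                                   down.segment_predictions.raw_scores,
                                   atol=1e-6)

    def test_too_short_signal_rejected(self):
        record, _ = synth_record(SynthConfig(seed=25, duration_s=5))
        sig = harmonize_signal(record.signals[0])
        with pytest.raises(ValueError):
            predict_sample(ColumnMeanModel(), sig)
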