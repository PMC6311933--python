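import numpy as np
import pytest

from m6awin.autograd import Tensor
from m6awin.encode import encode_batch, pad_width
from m6awin.interpret import (
    SaliencyTrack,
    distance_to_nearest_site,
    filters_to_motifs,
    information_content,
    most_salient_nucleotide,
    rank_motifs,
    saliency,
    site_saliency_percentile,
)
from m6awin.model import ModelConfig, build_model

from oracles import brute_force_motifs


def toy_model(filters: np.ndarray, biases: np.ndarray | None = None):
    """Model whose first conv block computes exactly ReLU(conv).

    Batch norm is neutralized (running_var set so the eps term cancels)
    so activations match the plain scan the brute-force oracle performs.
    """
    n_filters, _, flen = filters.shape
    cfg = ModelConfig(
        filter_sizes=(flen, 2),
        filter_counts=(n_filters, 2),
        blstm_units=2,
        fc_units=2,
        dropout_rate=0.0,
        patience=1,
        max_epochs=1,
        seed=0,
    )
    model = build_model(cfg)
    model.conv1_w.data = filters.astype(np.float64)
    model.conv1_b.data = (
        np.zeros(n_filters) if biases is None else biases.astype(np.float64)
    )
    model.bn1.running_mean[:] = 0.0
    model.bn1.running_var[:] = 1.0 - model.bn1.eps
    return model


class TestFiltersToMotifs:
    def test_single_sequence_alpha_cancels(self):
        # filter fires (alpha=2) only on the exact subsequence ACGUA
        filters = np.zeros((1, 4, 5))
        for offset, base in enumerate("ACGUA"):
            filters[0, "ACGU".index(base), offset] = 1.0
        model = toy_model(filters, biases=np.array([-3.0]))
        motifs = filters_to_motifs(model, ["ACGUACGUAC"])
        assert motifs[0].support == 1
        expected = np.zeros((5, 4))
        for offset, base in enumerate("ACGUA"):
            expected[offset, "ACGU".index(base)] = 1.0
        np.testing.assert_allclose(motifs[0].pwm, expected)

    def test_two_sequences_weighted_rows(self):
        # filter responds 1.0 to all-A windows, 3.0 to all-C windows
        filters = np.zeros((1, 4, 4))
        filters[0, 0, :] = 0.25  # A channel: 4 * 0.25 = 1
        filters[0, 1, :] = 0.75  # C channel: 4 * 0.75 = 3
        model = toy_model(filters)
        motifs = filters_to_motifs(model, ["AAAAAAAA", "CCCCCCCC"])
        assert motifs[0].support == 2
        # every row: 1*(1,0,0,0) + 3*(0,1,0,0), normalized
        for row in motifs[0].pwm:
            np.testing.assert_allclose(row, [0.25, 0.75, 0.0, 0.0])

    def test_never_positive_filter_excluded(self):
        filters = np.zeros((2, 4, 4))
        filters[0] = -1.0  # can never activate
        filters[1, 0, 0] = 1.0
        model = toy_model(filters, biases=np.array([-10.0, 0.0]))
        motifs = filters_to_motifs(model, ["ACGUACGU"])
        assert motifs[0].support == 0 and motifs[0].pwm is None
        assert motifs[1].support == 1
        assert [m.filter_index for m in rank_motifs(motifs)] == [1]

    @pytest.mark.parametrize("fraction", [0.0, 0.5])
    def test_matches_brute_force_oracle(self, rng, fraction):
        filters = rng.normal(size=(2, 4, 6))
        biases = rng.normal(size=2)
        sequences = [
            "".join(rng.choice(list("ACGU"), rng.integers(8, 20)))
            for _ in range(10)
        ]
        model = toy_model(filters, biases)
        motifs = filters_to_motifs(model, sequences, activation_fraction=fraction)
        expected = brute_force_motifs(filters, biases, sequences, fraction)
        for motif, (cumulative, pwm, support) in zip(motifs, expected):
            assert motif.support == support
            np.testing.assert_allclose(motif.cumulative, cumulative, atol=1e-12)
            if pwm is None:
                assert motif.pwm is None
            else:
                np.testing.assert_allclose(motif.pwm, pwm, atol=1e-12)

    def test_empty_input_raises(self):
        model = toy_model(np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            filters_to_motifs(model, [])


class TestRanking:
    def test_information_content_bounds(self):
        flat = np.full((5, 4), 0.25)
        sharp = np.eye(4)[[0, 2, 0, 1, 3]].astype(float)
        assert information_content(flat) == pytest.approx(0.0, abs=1e-9)
        assert information_content(sharp) == pytest.approx(10.0, abs=1e-6)


class _LinearSurrogate:
    """Duck-typed stand-in whose logit is exactly linear: sum(W * X)."""

    def __init__(self, weights: np.ndarray, filter_size: int = 10):
        self.weights = weights
        self.config = ModelConfig()

    def logit_and_input_gradient(self, sequence):
        f1 = self.config.filter_sizes[0]
        x, _ = encode_batch([sequence], f1)
        pad = pad_width(f1)
        xt = Tensor(x[0], requires_grad=True)
        w_full = np.zeros_like(x[0])
        w_full[:, pad : pad + len(sequence)] = self.weights
        logit = (xt * w_full).sum()
        logit.backward()
        return float(logit.data), xt.grad


class TestSaliency:
    def test_exact_on_linear_surrogate(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 20))
        weights = rng.normal(size=(4, 20))
        model = _LinearSurrogate(weights)
        track = saliency(model, seq)
        for j, base in enumerate(seq):
            assert track.scores[j] == pytest.approx(
                abs(weights["ACGU".index(base), j]), abs=1e-12
            )

    def test_n_positions_score_zero(self, rng):
        weights = rng.normal(size=(4, 9))
        track = saliency(_LinearSurrogate(weights), "ACGNNNACG")
        assert np.all(track.scores[3:6] == 0)
        assert np.all(track.scores[:3] > 0)

    def test_finite_difference_on_real_model(self, trained_small, rng):
        model, _ = trained_small
        seq = "".join(rng.choice(list("ACGU"), 101))
        track = saliency(model, seq)
        f1 = model.config.filter_sizes[0]
        pad = pad_width(f1)
        x, lengths = encode_batch([seq], f1)
        eps = 1e-4
        for j in rng.choice(101, size=5, replace=False):
            channel = "ACGU".index(seq[j])
            up, down = x.copy(), x.copy()
            up[0, channel, pad + j] += eps
            down[0, channel, pad + j] -= eps
            numeric = (
                model.forward(Tensor(up), lengths).data[0]
                - model.forward(Tensor(down), lengths).data[0]
            ) / (2 * eps)
            assert abs(abs(numeric) - track.scores[j]) <= 1e-3 * max(
                1e-8, abs(numeric)
            )

    def test_all_n_window_zero_track(self, trained_small):
        model, _ = trained_small
        track = saliency(model, "N" * 50)
        assert np.all(track.scores == 0)
        assert most_salient_nucleotide(track) is None


def make_track(sequence, scores):
    return SaliencyTrack(
        window_id="w",
        sequence=sequence,
        scores=np.asarray(scores, dtype=float),
        class_score=0.0,
        gradient=np.zeros((4, len(sequence))),
    )


class TestMostSalient:
    def test_argmax(self):
        assert most_salient_nucleotide(make_track("ACG", [0.1, 0.9, 0.3])) == (
            1, "C", 0.9,
        )

    def test_tie_leftmost(self):
        assert most_salient_nucleotide(make_track("AC", [0.5, 0.5]))[0] == 0

    def test_all_zero_none(self):
        assert most_salient_nucleotide(make_track("AC", [0.0, 0.0])) is None


class TestSitePercentile:
    def test_unique_max_among_ten_as(self):
        scores = [0.1 * i for i in range(10)]
        track = make_track("A" * 10, scores)
        [(off, pct, flagged)] = site_saliency_percentile(track, [9])
        assert pct == pytest.approx(0.95)
        assert not flagged

    def test_full_tie_half(self):
        track = make_track("A" * 6, [0.3] * 6)
        [(_, pct, _)] = site_saliency_percentile(track, [2])
        assert pct == pytest.approx(0.5)

    def test_single_a_self_tie(self):
        track = make_track("CAC", [0.1, 0.9, 0.2])
        [(_, pct, _)] = site_saliency_percentile(track, [1])
        assert pct == pytest.approx(0.5)

    def test_non_a_site_flagged(self):
        track = make_track("ACGA", [0.1, 0.9, 0.2, 0.3])
        with pytest.warns(UserWarning, match="not A"):
            [(_, pct, flagged)] = site_saliency_percentile(track, [1])
        assert flagged
        # among all 4 positions: 3 below + half of 1 tie = 0.875
        assert pct == pytest.approx(0.875)


class TestDistance:
    def test_downstream(self):
        assert distance_to_nearest_site(10, [7, 30]) == 3

    def test_on_site(self):
        assert distance_to_nearest_site(7, [7]) == 0

    def test_tie_negative(self):
        assert distance_to_nearest_site(10, [5, 15]) == -5

    def test_empty_none(self):
        assert distance_to_nearest_site(10, []) is None
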