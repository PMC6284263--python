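"""LSTM cell, Bi-LSTM encoder, CRF layer, and tagger training."""

import itertools

import numpy as np
import pytest

from disner.synthetic import FixtureConfig, generate_ner_corpus
from disner.tagger import (
    K,
    LABELS,
    START,
    STOP,
    LSTMCellParams,
    TaggerConfig,
    TaggerModel,
    bilstm_encode,
    crf_nll,
    emission_scores,
    load_tagger,
    log_partition,
    lstm_step,
    nll_loss,
    save_tagger,
    sequence_score,
    tag_document,
    train_tagger,
    viterbi_decode,
)


def zero_cell(H, D):
    zeros = {
        name: np.zeros((H, D)) if name.startswith("W_x")
        else np.zeros((H, H)) if name.startswith("W_")
        else np.zeros(H)
        for name in ("W_xi", "W_hi", "W_ci", "b_i", "W_xc", "W_hc", "b_c",
                     "W_xo", "W_ho", "W_co", "b_o")
    }
    return LSTMCellParams(**zeros)


def scalar_loop_lstm(x, h_prev, c_prev, cell):
    """Independent elementwise transcription of the coupled-gate recurrence."""
    H = len(h_prev)

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    i = np.empty(H)
    g = np.empty(H)
    c = np.empty(H)
    o = np.empty(H)
    h = np.empty(H)
    for j in range(H):
        ai = cell.b_i[j]
        ag = cell.b_c[j]
        for d in range(len(x)):
            ai += cell.W_xi[j, d] * x[d]
            ag += cell.W_xc[j, d] * x[d]
        for m in range(H):
            ai += cell.W_hi[j, m] * h_prev[m] + cell.W_ci[j, m] * c_prev[m]
            ag += cell.W_hc[j, m] * h_prev[m]
        i[j] = sig(ai)
        g[j] = np.tanh(ag)
        c[j] = (1 - i[j]) * c_prev[j] + i[j] * g[j]
    for j in range(H):
        ao = cell.b_o[j]
        for d in range(len(x)):
            ao += cell.W_xo[j, d] * x[d]
        for m in range(H):
            ao += cell.W_ho[j, m] * h_prev[m] + cell.W_co[j, m] * c[m]
        o[j] = sig(ao)
        h[j] = o[j] * np.tanh(c[j])
    return h, c


def random_instance(rng, n):
    return rng.normal(size=(n, K)), rng.normal(size=(K + 2, K + 2))


def brute_force_paths(P, A):
    n = P.shape[0]
    return {
        y: sequence_score(P, A, y)
        for y in itertools.product(range(K), repeat=n)
    }


class TestLSTMCell:
    def test_zero_everything(self):
        cell = zero_cell(3, 2)
        h, c = lstm_step(np.zeros(2), np.zeros(3), np.zeros(3), cell)
        assert np.allclose(h, 0) and np.allclose(c, 0)

    def test_coupled_forget_halves_carried_cell(self):
        # zero params: i = 0.5, so c_t = 0.5 * c_prev and h = 0.5 * tanh(c_t)
        cell = zero_cell(3, 2)
        h, c = lstm_step(np.zeros(2), np.zeros(3), 2.0 * np.ones(3), cell)
        assert np.allclose(c, 1.0)
        assert np.allclose(h, 0.5 * np.tanh(1.0))

    def test_matches_scalar_loop_transcription(self, rng):
        for _ in range(10):
            H, D = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            cell = LSTMCellParams.init(D, H, rng)
            for arr in cell.arrays().values():
                arr += rng.normal(scale=0.3, size=arr.shape)
            x = rng.normal(size=D)
            h_prev = rng.normal(size=H)
            c_prev = rng.normal(size=H)
            h, c = lstm_step(x, h_prev, c_prev, cell)
            h_ref, c_ref = scalar_loop_lstm(x, h_prev, c_prev, cell)
            assert np.max(np.abs(h - h_ref)) < 1e-12
            assert np.max(np.abs(c - c_ref)) < 1e-12

    def test_shape_mismatch(self, rng):
        cell = LSTMCellParams.init(2, 3, rng)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(4), np.zeros(3), np.zeros(3), cell)


def small_model(rng, D=4, H=3, use_bilstm=True, use_crf=True, seed=0):
    cfg = TaggerConfig(word_dim=D, hidden_dim=H, dropout=0.0, seed=seed,
                       use_bilstm=use_bilstm, use_crf=use_crf)
    return TaggerModel.init(["alpha", "beta", "gamma"], cfg)


class TestBiLSTM:
    def test_single_token_concatenates_both_directions(self, rng):
        model = small_model(rng)
        x = rng.normal(size=(1, 4))
        out = bilstm_encode(x, model)
        hf, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), model.forward_cell)
        hb, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), model.backward_cell)
        assert np.allclose(out[0], np.concatenate([hf, hb]))

    def test_palindrome_symmetry_with_shared_cells(self, rng):
        model = small_model(rng)
        model.backward_cell = model.forward_cell
        x = rng.normal(size=(2, 4))
        xs = np.vstack([x, x[::-1]])  # palindromic sequence
        out = bilstm_encode(xs, model)
        H = 3
        swapped = np.concatenate([out[::-1, H:], out[::-1, :H]], axis=1)
        assert np.allclose(out, swapped)

    def test_equals_two_independent_unidirectional_runs(self, rng):
        model = small_model(rng)
        xs = rng.normal(size=(5, 4))
        out = bilstm_encode(xs, model)

        def run(cell, order):
            h = np.zeros(3)
            c = np.zeros(3)
            states = {}
            for t in order:
                h, c = lstm_step(xs[t], h, c, cell)
                states[t] = h
            return states

        fwd = run(model.forward_cell, range(5))
        bwd = run(model.backward_cell, range(4, -1, -1))
        for t in range(5):
            assert np.allclose(out[t], np.concatenate([fwd[t], bwd[t]]))

    def test_empty_sentence_rejected(self, rng):
        with pytest.raises(ValueError):
            bilstm_encode(np.zeros((0, 4)), small_model(rng))


class TestCRF:
    def test_emission_shape_and_zero_projection(self, rng):
        model = small_model(rng)
        model.emission_W[:] = 0
        model.emission_b[:] = 0
        ctx = rng.normal(size=(4, 6))
        P = emission_scores(ctx, model)
        assert P.shape == (4, 3)
        assert np.allclose(P, 0)

    def test_identity_projection_passes_context_through(self, rng):
        model = small_model(rng)
        model.emission_W = np.hstack([np.eye(3), np.zeros((3, 3))])
        model.emission_b = np.zeros(3)
        ctx = rng.normal(size=(2, 6))
        assert np.allclose(emission_scores(ctx, model), ctx[:, :3])

    def test_zero_instance_scores(self):
        P = np.zeros((3, K))
        A = np.zeros((K + 2, K + 2))
        for y in itertools.product(range(K), repeat=3):
            assert sequence_score(P, A, y) == 0.0
        assert log_partition(P, A) == pytest.approx(3 * np.log(3.0), abs=1e-12)

    def test_single_token_score_and_partition(self, rng):
        P, A = random_instance(rng, 1)
        A0 = np.zeros_like(A)
        assert sequence_score(P, A0, [2]) == pytest.approx(P[0, 2])
        boundary = P[0] + A[START, :K] + A[:K, STOP]
        from scipy.special import logsumexp
        assert log_partition(P, A) == pytest.approx(float(logsumexp(boundary)))

    def test_sequence_score_matches_loop_oracle(self, rng):
        P, A = random_instance(rng, 3)
        y = [1, 0, 2]
        expected = A[START, 1] + P[0, 1] + A[1, 0] + P[1, 0] + A[0, 2] + P[2, 2] + A[2, STOP]
        assert sequence_score(P, A, y) == pytest.approx(expected, abs=1e-12)

    def test_viterbi_ties_break_to_b(self):
        P = np.zeros((1, K))
        A = np.zeros((K + 2, K + 2))
        y, score = viterbi_decode(P, A)
        assert y == [0] and score == 0.0
        y4, s4 = viterbi_decode(np.zeros((4, K)), A)
        assert y4 == [0, 0, 0, 0] and s4 == 0.0

    def test_viterbi_against_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 7))
            P, A = random_instance(rng, n)
            scores = brute_force_paths(P, A)
            y, s = viterbi_decode(P, A)
            assert s == pytest.approx(max(scores.values()), abs=1e-10)
            assert s == pytest.approx(sequence_score(P, A, y), abs=1e-10)

    def test_viterbi_beats_sampled_paths(self, rng):
        P, A = random_instance(rng, 9)
        _, s = viterbi_decode(P, A)
        for _ in range(1000):
            y = list(rng.integers(0, K, size=9))
            assert s >= sequence_score(P, A, y) - 1e-12

    def test_constrain_bio_blocks_o_to_i(self, rng):
        O, I = LABELS.index("O"), LABELS.index("I")
        for _ in range(50):
            P, A = random_instance(rng, 6)
            A[O, I] = 10.0  # make O->I attractive
            y, _ = viterbi_decode(P, A, constrain_bio=True)
            assert all(not (a == O and b == I) for a, b in zip(y, y[1:]))

    def test_probabilities_normalize(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 7))
            P, A = random_instance(rng, n)
            logZ = log_partition(P, A)
            total = sum(np.exp(s - logZ) for s in brute_force_paths(P, A).values())
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_nll_zero_model_is_uniform(self):
        P = np.zeros((4, K))
        A = np.zeros((K + 2, K + 2))
        loss, _, _ = crf_nll(P, A, [0, 1, 2, 0])
        assert loss == pytest.approx(4 * np.log(3.0), abs=1e-12)

    def test_nll_vanishes_for_peaked_emissions(self):
        gold = [0, 1, 2]
        P = np.full((3, K), -50.0)
        for t, g in enumerate(gold):
            P[t, g] = 50.0
        loss, _, _ = crf_nll(P, np.zeros((K + 2, K + 2)), gold)
        assert 0 <= loss < 1e-8

    def test_nll_nonnegative_for_any_gold(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            P, A = random_instance(rng, n)
            gold = list(rng.integers(0, K, size=n))
            loss, _, _ = crf_nll(P, A, gold)
            assert loss >= -1e-12

    def test_illegal_gold_rejected(self, rng):
        P, A = random_instance(rng, 2)
        with pytest.raises(ValueError):
            crf_nll(P, A, [0, 5])


class TestFullModelGradients:
    def test_gradients_match_finite_differences(self, rng):
        model = small_model(rng, D=3, H=2, seed=7)
        ids = model.word_ids(["alpha", "beta", "nope", "gamma"])
        gold = [0, 1, 2, 0]
        loss, grads = nll_loss(model, ids, gold)
        assert loss > 0
        h = 1e-5
        for name, arr in model.parameters().items():
            flat_idx = list(np.ndindex(*arr.shape))
            for idx in flat_idx[:: max(1, len(flat_idx) // 10)]:
                orig = arr[idx]
                arr[idx] = orig + h
                up, _ = nll_loss(model, ids, gold)
                arr[idx] = orig - h
                down, _ = nll_loss(model, ids, gold)
                arr[idx] = orig
                num = (up - down) / (2 * h)
                denom = max(1.0, abs(num))
                assert abs(num - grads[name][idx]) / denom < 1e-4, name

    def test_dropout_mask_scales_gradients(self, rng):
        model = small_model(rng, D=3, H=2)
        ids = model.word_ids(["alpha", "beta"])
        mask = np.zeros((2, 3))
        loss, grads = nll_loss(model, ids, [0, 1], dropout_mask=mask)
        assert np.allclose(grads["embedding"], 0)


class TestTraining:
    def test_zero_learning_rate_keeps_parameters(self, small_corpus):
        cfg = dict(word_dim=6, hidden_dim=4, dropout=0.0, learning_rate=0.0, seed=1)
        m1 = train_tagger(small_corpus[:3], None, None, TaggerConfig(epochs=1, **cfg))
        m3 = train_tagger(small_corpus[:3], None, None, TaggerConfig(epochs=3, **cfg))
        for k, a in m1.parameters().items():
            assert np.array_equal(a, m3.parameters()[k]), k

    def test_training_is_deterministic(self, small_corpus):
        cfg = TaggerConfig(word_dim=6, hidden_dim=4, epochs=2, seed=3)
        m1 = train_tagger(small_corpus[:4], None, None, cfg)
        m2 = train_tagger(small_corpus[:4], None, None, cfg)
        for k, a in m1.parameters().items():
            assert np.array_equal(a, m2.parameters()[k]), k

    def test_loss_decreases_early(self, small_corpus):
        log = []
        cfg = TaggerConfig(word_dim=8, hidden_dim=5, dropout=0.0,
                           learning_rate=0.02, epochs=5, seed=2)
        train_tagger(small_corpus, None, None, cfg, log=log)
        losses = [r["loss"] for r in log]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_tagger([], None, None, TaggerConfig())

    def test_no_crf_ablation_yields_legal_mentions(self, small_corpus):
        cfg = TaggerConfig(word_dim=6, hidden_dim=4, epochs=2, seed=0, use_crf=False)
        model = train_tagger(small_corpus[:4], None, None, cfg)
        for doc in small_corpus[4:]:
            mentions = tag_document(model, doc)
            ordered = sorted(mentions)
            for a, b in zip(ordered, ordered[1:]):
                assert not a.overlaps(b)
            for m in mentions:
                assert doc.text[m.start:m.end] == m.text

    def test_no_bilstm_ablation_trains(self, small_corpus):
        cfg = TaggerConfig(word_dim=6, hidden_dim=4, epochs=2, seed=0, use_bilstm=False)
        model = train_tagger(small_corpus[:4], None, None, cfg)
        assert "fwd.W_xi" not in model.parameters()
        tag_document(model, small_corpus[4])

    def test_dev_selection_returns_best_epoch(self, small_corpus):
        log = []
        cfg = TaggerConfig(word_dim=8, hidden_dim=5, learning_rate=0.1,
                           epochs=4, seed=0)
        train_tagger(small_corpus[:6], small_corpus[6:], None, cfg, log=log)
        assert all("dev_f1" in r for r in log)

    def test_checkpoint_roundtrip(self, small_corpus, tmp_path):
        cfg = TaggerConfig(word_dim=6, hidden_dim=4, epochs=1, seed=0)
        model = train_tagger(small_corpus[:3], None, None, cfg)
        path = tmp_path / "model.json"
        save_tagger(model, path)
        loaded = load_tagger(path)
        assert loaded.words == model.words
        for k, a in model.parameters().items():
            assert np.array_equal(a, loaded.parameters()[k]), k
        doc = small_corpus[3]
        assert tag_document(loaded, doc) == tag_document(model, doc)
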