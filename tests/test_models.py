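"""Model correctness: closed-form limits, hand-computed oracles, invariants."""

import numpy as np
import pytest

from ehrisk.encoding import EncodedSample
from ehrisk.models import (ModelConfig, RETAIN, StandardLSTM, TLSTM,
                           LogisticBaseline, default_time_decay, lr_forward,
                           load_model, make_batch, save_model)

from helpers import retain_scalar_forward, tlstm_scalar_forward


def sample(visits, elapsed=None, static=(), y=0, pid="T"):
    if elapsed is None:
        elapsed = [0] + [10] * (len(visits) - 1)
    off = sum(elapsed)            # oldest visit's days-before-index
    offsets = []
    for e in elapsed:
        off -= e
        offsets.append(off)
    return EncodedSample(patient_id=pid, y=y,
                         visit_indices=[list(v) for v in visits],
                         offsets=offsets, elapsed=list(elapsed),
                         static_indices=list(static))


SMALL = dict(vocab_size=12, embed_dim=6, hidden_size=5, dropout=0.0,
             n_layers=2, seed=3)


class TestTimeDecay:
    def test_unit_at_zero_gap(self):
        assert default_time_decay(np.array(0.0)) == 1.0

    def test_monotone_decreasing_and_positive(self):
        gaps = np.array([0.0, 1, 7, 30, 90, 365])
        g = default_time_decay(gaps)
        assert np.all(np.diff(g) < 0)
        assert np.all((g > 0) & (g <= 1))

    def test_discounted_short_term_memory_shrinks_with_gap(self):
        cs = np.array([0.7, -0.4])
        norms = [np.linalg.norm(cs * default_time_decay(np.array(d)))
                 for d in [0.0, 10.0, 100.0]]
        assert norms[0] > norms[1] > norms[2]


class TestTLSTM:
    def test_reduces_to_lstm_bit_exactly_at_zero_gaps(self):
        cfg = ModelConfig(**SMALL)
        tlstm = TLSTM(cfg)
        lstm = StandardLSTM(cfg)
        state = tlstm.get_state()
        lstm.set_state({k: state[k] for k in lstm.weights})
        s = sample([[1, 2], [3], [4, 5, 6]], elapsed=[0, 0, 0])
        batch = make_batch([s])
        assert np.array_equal(tlstm.forward_batch(batch).data,
                              lstm.forward_batch(batch).data)

    def test_nonzero_gap_changes_output(self):
        cfg = ModelConfig(**SMALL)
        m = TLSTM(cfg)
        p0 = m.forward_batch(make_batch([sample([[1], [2]], elapsed=[0, 0])])).data
        p1 = m.forward_batch(make_batch([sample([[1], [2]], elapsed=[0, 60])])).data
        assert not np.array_equal(p0, p1)

    def test_matches_hand_computed_scalar_cell(self):
        cfg = ModelConfig(vocab_size=4, embed_dim=1, hidden_size=1,
                          dropout=0.0, n_layers=1, seed=0)
        m = TLSTM(cfg)
        w = {"wi": 0.6, "wf": -0.3, "wc": 0.9, "wo": 0.2,
             "ui": 0.1, "uf": 0.4, "uc": -0.5, "uo": 0.3,
             "bi": 0.05, "bf": 0.6, "bc": -0.1, "bo": 0.0,
             "wd": 0.8, "bd": -0.2, "w_out": 1.4, "b_out": -0.3}
        m.weights["E"].data[:] = [[0.0], [0.5], [-0.7], [0.3]]
        m.weights["W0"].data[:] = [[w["wi"], w["wf"], w["wc"], w["wo"]]]
        m.weights["U0"].data[:] = [[w["ui"], w["uf"], w["uc"], w["uo"]]]
        m.weights["b0"].data[:] = [w["bi"], w["bf"], w["bc"], w["bo"]]
        m.weights["Wd0"].data[:] = [[w["wd"]]]
        m.weights["bd0"].data[:] = [w["bd"]]
        m.weights["w_out"].data[:] = [[w["w_out"]]]
        m.weights["b_out"].data[:] = [w["b_out"]]
        # visit 1 = tokens {1,2} (0.5 - 0.7), visit 2 = {3}, visit 3 = {1}
        s = sample([[1, 2], [3], [1]], elapsed=[0, 30, 90])
        got = float(m.forward_batch(make_batch([s])).data[0])
        want = tlstm_scalar_forward(w, [-0.2, 0.3, 0.5], [0.0, 30.0, 90.0])
        assert got == pytest.approx(want, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty sequence"):
            make_batch([EncodedSample("x", 0, [], [], [], [])])

    def test_negative_elapsed_rejected(self):
        bad = EncodedSample("x", 0, [[1]], [0], [-1], [])
        with pytest.raises(ValueError):
            make_batch([bad])


class TestRETAIN:
    def test_alpha_sums_to_one_with_padding(self):
        cfg = ModelConfig(**SMALL)
        m = RETAIN(cfg)
        batch = make_batch([sample([[1], [2], [3]]), sample([[4]])])
        _, alpha, _ = m.forward_batch(batch, return_attention=True)
        assert np.all(alpha >= 0)
        np.testing.assert_allclose(alpha.sum(axis=1), [1.0, 1.0], atol=1e-12)
        assert np.all(alpha[1, 1:] == 0)          # padded visits get no weight

    def test_single_visit_alpha_is_one(self):
        m = RETAIN(ModelConfig(**SMALL))
        out = m.forward(sample([[1, 2]]))
        np.testing.assert_array_equal(out.alpha, [[1.0]])
        assert 0.0 < out.probability[0] < 1.0

    def test_matches_hand_computed_two_visit_toy(self):
        cfg = ModelConfig(vocab_size=4, embed_dim=1, hidden_size=1,
                          dropout=0.0, n_layers=2, seed=0)
        m = RETAIN(cfg)
        w = {}
        for pre in ("a_", "b_"):
            vals = {"wi": 0.3, "wf": -0.2, "wc": 0.7, "wo": 0.4,
                    "ui": 0.2, "uf": 0.1, "uc": -0.3, "uo": 0.5,
                    "bi": 0.0, "bf": 0.2, "bc": 0.1, "bo": -0.1}
            if pre == "b_":
                vals = {k: v * 0.8 for k, v in vals.items()}
            for k, v in vals.items():
                w[pre + k] = v
            m.weights[f"{pre}W0"].data[:] = [[vals["wi"], vals["wf"],
                                              vals["wc"], vals["wo"]]]
            m.weights[f"{pre}U0"].data[:] = [[vals["ui"], vals["uf"],
                                              vals["uc"], vals["uo"]]]
            m.weights[f"{pre}b0"].data[:] = [vals["bi"], vals["bf"],
                                             vals["bc"], vals["bo"]]
        w.update({"w_alpha": 1.1, "b_alpha": 0.2, "W_beta": 0.9,
                  "b_beta": -0.1, "w_out": 1.3, "b_out": 0.15})
        m.weights["E"].data[:] = [[0.0], [0.6], [-0.4], [0.2]]
        for name in ("w_alpha", "b_alpha", "W_beta", "b_beta", "w_out", "b_out"):
            m.weights[name].data[:] = np.reshape(w[name], m.weights[name].shape)
        s = sample([[1], [2, 3]])
        got = float(m.forward_batch(make_batch([s])).data[0])
        want = retain_scalar_forward(w, [0.6, -0.2])
        assert got == pytest.approx(want, abs=1e-12)


@pytest.mark.parametrize("cls", [TLSTM, RETAIN])
class TestSharedInvariants:
    def test_token_order_within_visit_irrelevant(self, cls):
        m = cls(ModelConfig(**SMALL))
        a = m.forward_batch(make_batch([sample([[1, 2, 3], [4, 5]])])).data
        b = m.forward_batch(make_batch([sample([[3, 1, 2], [5, 4]])])).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_eval_mode_deterministic(self, cls):
        m = cls(ModelConfig(**SMALL))
        s = [sample([[1], [2, 3]]), sample([[4, 5]])]
        assert np.array_equal(m.predict_proba(s), m.predict_proba(s))

    def test_dropout_only_active_in_training(self, cls):
        m = cls(ModelConfig(**{**SMALL, "dropout": 0.5}))
        batch = make_batch([sample([[1], [2]])])
        t1 = m.forward_batch(batch, training=True).data
        t2 = m.forward_batch(batch, training=True).data
        assert not np.array_equal(t1, t2)
        e1 = m.forward_batch(batch, training=False).data
        e2 = m.forward_batch(batch, training=False).data
        assert np.array_equal(e1, e2)

    def test_checkpoint_round_trip(self, cls, tmp_path):
        cfg = ModelConfig(**SMALL)
        m = cls(cfg)
        s = [sample([[1, 2], [3]])]
        path = str(tmp_path / "model.npz")
        save_model(m, path)
        again = load_model(path, cfg)
        assert np.array_equal(m.predict_proba(s), again.predict_proba(s))
        with pytest.raises(ValueError, match="hash"):
            load_model(path, ModelConfig(**{**SMALL, "hidden_size": 7}))


class TestLogisticBaseline:
    def test_all_zero_features_give_sigmoid_intercept(self):
        coef = np.array([0.5, -0.2])
        assert lr_forward(np.zeros(2), coef, 0.3) == pytest.approx(
            1 / (1 + np.exp(-0.3)))

    def test_separable_data_reaches_perfect_training_auroc(self):
        from sklearn.metrics import roc_auc_score
        pos = [sample([[1]], y=1, pid=f"p{i}") for i in range(20)]
        neg = [sample([[2]], y=0, pid=f"n{i}") for i in range(20)]
        clf = LogisticBaseline(vocab_size=4).fit(pos + neg)
        scores = clf.predict_proba(pos + neg)
        assert roc_auc_score([s.y for s in pos + neg], scores) == 1.0

    def test_planted_effect_signs_recovered(self, small_cohort):
        vocab = small_cohort["vocab"]
        clf = LogisticBaseline(len(vocab)).fit(small_cohort["encoded"])
        risk = clf.coef_[vocab.encode("RX:DB90001")]
        prot = clf.coef_[vocab.encode("RX:DB90002")]
        assert risk > 0 > prot
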