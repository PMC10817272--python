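"""Feature-contribution statistics: FC, normalization, RC, Wilcoxon, BH."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ehrisk import contribution as ct
from ehrisk.encoding import VocabMap
from ehrisk.models import ModelConfig, TLSTM, make_batch

from helpers import tlstm_scalar_forward
from test_models import sample


class PresenceStub:
    """p = 0.5 + 0.1 per distinct marker token present (tokens 1 and 2)."""

    def predict_proba(self, samples):
        out = []
        for s in samples:
            toks = {i for v in s.visit_indices for i in v} | set(s.static_indices)
            out.append(0.5 + 0.1 * len(toks & {1, 2}))
        return np.array(out)


class TestRawFeatureContribution:
    def test_stub_model_delta(self):
        s = sample([[1, 3], [4]])
        assert ct.raw_feature_contribution(PresenceStub(), s, 1) == \
            pytest.approx(0.1)

    def test_uninfluential_token_has_zero_fc(self):
        s = sample([[1, 3], [4]])
        assert ct.raw_feature_contribution(PresenceStub(), s, 3) == 0.0

    def test_absent_token_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            ct.raw_feature_contribution(PresenceStub(), sample([[1]]), 9)

    def test_per_occurrence_mode_sums_hand_computed_deltas(self):
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
        # token 1 occurs in both visits alongside fillers 2 and 3
        s = sample([[1, 2], [1, 3]], elapsed=[0, 30])
        full = tlstm_scalar_forward(w, [0.5 - 0.7, 0.5 + 0.3], [0.0, 30.0])
        minus_first = tlstm_scalar_forward(w, [-0.7, 0.5 + 0.3], [0.0, 30.0])
        minus_second = tlstm_scalar_forward(w, [0.5 - 0.7, 0.3], [0.0, 30.0])
        want = (full - minus_first) + (full - minus_second)
        got = ct.raw_feature_contribution(m, s, 1, mode="per_occurrence")
        assert got == pytest.approx(want, abs=1e-12)

    def test_all_occurrence_removal_drops_emptied_visits(self):
        s = sample([[1], [2, 1]], elapsed=[0, 15])
        pert = ct.remove_token(s, 1)
        assert pert.visit_indices == [[2]]
        assert pert.elapsed == [0]


class TestNormalizeFC:
    @pytest.mark.parametrize("raw,want", [
        ({"a": 2.0, "b": 3.0, "c": 5.0}, {"a": 0.2, "b": 0.3, "c": 0.5}),
        ({"a": 0.0, "b": 0.0}, {"a": 0.0, "b": 0.0}),
        ({"a": -1.0, "b": 3.0}, {"a": -0.25, "b": 0.75}),
    ])
    def test_examples(self, raw, want):
        got = ct.normalize_fc(raw)
        assert got == pytest.approx(want)

    @pytest.mark.parametrize("seed", range(4))
    def test_absolute_values_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        raw = {f"t{i}": v for i, v in enumerate(rng.normal(size=8))}
        norm = ct.normalize_fc(raw)
        assert sum(abs(v) for v in norm.values()) == pytest.approx(1.0)


class TestRelativeContribution:
    def test_median_ratio(self):
        assert ct.rc_value([0.2, 0.4, 0.6], [0.1, 0.2, 0.3]) == pytest.approx(2.0)

    def test_identical_lists_give_unity(self):
        assert ct.rc_value([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_zero_denominator_signals_undefined(self):
        assert ct.rc_value([0.5], [0.0]) is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ct.rc_value([], [1.0])

    def test_scaling_examples(self):
        assert ct.scale_rc({"PTSD": 0.8, "X": 1.6}, "PTSD") == \
            pytest.approx({"PTSD": 1.0, "X": 2.0})
        assert ct.scale_rc({"PTSD": 1.0, "X": 0.5}, "PTSD") == \
            pytest.approx({"PTSD": 1.0, "X": 0.5})

    def test_undefined_reference_rejected(self):
        with pytest.raises(ValueError):
            ct.scale_rc({"PTSD": None, "X": 0.5}, "PTSD")

    @pytest.mark.parametrize("seed", range(4))
    def test_reference_exactly_one_after_scaling(self, seed):
        rng = np.random.default_rng(seed)
        table = {f"t{i}": float(v) for i, v in
                 enumerate(rng.uniform(0.1, 3.0, size=10))}
        scaled = ct.scale_rc(table, "t0")
        assert scaled["t0"] == 1.0


def _pairwise_u_pvalue(x, y):
    """Oracle: exact two-sided p from the Mann-Whitney U statistic computed
    by pairwise comparison, enumerated over all label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    centre = n1 * (len(pooled) - n1) / 2.0
    obs = abs(u_stat(range(n1)) - centre)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(comb) - centre) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_exact_small_sample(self):
        assert ct.wilcoxon_ranksum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_all_ties_give_p_one(self):
        assert ct.wilcoxon_ranksum([1, 1], [1, 1]) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_pairwise_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        x = list(rng.integers(0, 5, size=n1).astype(float))   # ties likely
        y = list(rng.integers(0, 5, size=n2).astype(float))
        assert ct.wilcoxon_ranksum(x, y) == pytest.approx(
            _pairwise_u_pvalue(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_branch_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = list(rng.normal(size=4))
        y = list(rng.normal(size=5))
        want = sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="exact").pvalue
        assert ct.wilcoxon_ranksum(x, y) == pytest.approx(want, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n10(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = list(rng.normal(size=5))
            y = list(rng.normal(0.5, size=5))
            exact = ct.wilcoxon_ranksum(x, y, exact_max_n=10)
            approx = ct.wilcoxon_ranksum(x, y, exact_max_n=0)
            assert abs(exact - approx) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ct.wilcoxon_ranksum([], [1.0])


def _bh_oracle(pvals):
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, pvals[i] * m / rank_from_top)
        q[i] = prev
    return q


class TestFdrAdjust:
    def test_hand_example(self):
        q, flags = ct.fdr_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
        assert flags.all()

    def test_single_p(self):
        q, flags = ct.fdr_adjust([0.04])
        assert q[0] == pytest.approx(0.04) and flags[0]
        q, flags = ct.fdr_adjust([0.5])
        assert not flags[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ct.fdr_adjust([0.1, 1.2])

    def test_matches_stepup_oracle_on_exhaustive_grid(self):
        grid = [0.01, 0.2, 0.8]
        for length in range(1, 7):
            for pvec in itertools.product(grid, repeat=length):
                q, _ = ct.fdr_adjust(list(pvec))
                np.testing.assert_allclose(q, _bh_oracle(np.array(pvec)),
                                           atol=1e-12)

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        q, _ = ct.fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCoefficientSummary:
    def test_t_statistic_arithmetic(self):
        vals = [0.10, 0.12, 0.11, 0.13, 0.09, 0.12, 0.10, 0.11, 0.13, 0.09]
        table = ct.summarize_coefficients({"nses": vals})
        row = table.iloc[0]
        assert row["Mean"] == pytest.approx(0.11)
        assert row["sd"] == pytest.approx(np.std(vals, ddof=1))
        t = row["Mean"] / (row["sd"] / math.sqrt(10))
        assert t == pytest.approx(23.335, abs=0.01)
        assert row["p"] < 1e-8
        assert row["Direction"] == "risk"

    def test_zero_variance_reported_as_sentinel(self):
        table = ct.summarize_coefficients({"x": [0.1] * 10})
        row = table.iloc[0]
        assert row["Mean"] == pytest.approx(0.1)
        assert row["sd"] == 0.0
        assert np.isnan(row["p"])


def _vocab(tokens):
    t2i = {t: i + 1 for i, t in enumerate(tokens)}
    return VocabMap(token_to_idx=t2i,
                    idx_to_token={i: t for t, i in t2i.items()},
                    freq={t: 1 for t in tokens}, reference_token="DX:F43")


def test_feature_report_shape_and_ranking_with_stub_model():
    rng = np.random.default_rng(0)
    vocab = _vocab(["DX:F43", "RX:RISK", "RX:OTHER"])
    samples = []
    for i in range(80):
        y = i % 2
        toks = [1]                       # reference in every patient
        if (y and rng.random() < 0.8) or (not y and rng.random() < 0.3):
            toks.append(2)
        if rng.random() < 0.5:
            toks.append(3)
        samples.append(sample([toks], y=y, pid=f"p{i}"))

    class Model:
        def predict_proba(self, ss):
            return np.array([0.1 + 0.5 * any(2 in v for v in s.visit_indices)
                             + 0.05 * any(1 in v for v in s.visit_indices)
                             + 0.01 * s.y for s in ss])

    report = ct.feature_report(Model(), samples, vocab, min_support=5)
    assert list(report.columns) == ct.REPORT_COLUMNS
    ref = report[report.Feature == "DX:F43"].iloc[0]
    assert ref.RelativeContribution == 1.0
    assert report["FDR_Q"].is_monotonic_increasing
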