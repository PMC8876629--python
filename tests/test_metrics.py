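import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hknot.detect import PseudoknotCandidate
from hknot.metrics import (
    ConfusionCounts,
    EvalRecord,
    confusion,
    core_stem_match,
    evaluate_dataset,
    parse_dotbracket,
    round3,
    score,
)

from .conftest import WORKED_FINAL_DB

# Printed (tp, tn, fp, fn) -> (ppv, recall, f1, mcc) rows, one block per
# platform group; reproduced exactly at 3-decimal half-up rounding.
REFERENCE_ROWS = [
    # entire dataset
    (3056, 3556, 1968, 2196, 0.608, 0.582, 0.595, 0.226),
    (4180, 3632, 1744, 1220, 0.706, 0.774, 0.738, 0.452),
    (3872, 3767, 1522, 1615, 0.718, 0.706, 0.712, 0.418),
    (5026, 3352, 1870, 528, 0.729, 0.905, 0.807, 0.569),
    (4212, 4102, 1162, 1300, 0.784, 0.764, 0.774, 0.543),
    (4214, 4101, 1160, 1301, 0.784, 0.764, 0.774, 0.543),
    # length < 30
    (738, 522, 118, 513, 0.862, 0.590, 0.701, 0.386),
    (904, 492, 156, 339, 0.853, 0.727, 0.785, 0.465),
    (916, 514, 124, 337, 0.881, 0.731, 0.799, 0.510),
    (1196, 469, 146, 80, 0.891, 0.937, 0.914, 0.722),
    (1244, 486, 134, 27, 0.903, 0.979, 0.939, 0.805),
    (1242, 485, 136, 28, 0.901, 0.978, 0.938, 0.802),
    # 30 <= length < 40
    (550, 832, 352, 587, 0.610, 0.484, 0.539, 0.191),
    (922, 851, 294, 254, 0.758, 0.784, 0.771, 0.528),
    (824, 823, 314, 360, 0.724, 0.696, 0.710, 0.420),
    (1078, 802, 324, 117, 0.769, 0.902, 0.830, 0.628),
    (988, 893, 296, 144, 0.769, 0.873, 0.818, 0.627),
    (988, 893, 296, 144, 0.769, 0.873, 0.818, 0.627),
    # 40 <= length < 50
    (612, 864, 478, 418, 0.561, 0.594, 0.577, 0.237),
    (792, 857, 510, 213, 0.608, 0.788, 0.687, 0.412),
    (764, 911, 410, 287, 0.651, 0.727, 0.687, 0.414),
    (904, 817, 524, 127, 0.633, 0.877, 0.735, 0.492),
    (764, 1010, 298, 300, 0.719, 0.718, 0.719, 0.490),
    (772, 1012, 290, 298, 0.727, 0.721, 0.724, 0.499),
    # length >= 50
    (1156, 1338, 1020, 678, 0.531, 0.630, 0.577, 0.196),
    (1562, 1432, 784, 414, 0.666, 0.790, 0.723, 0.439),
    (1368, 1519, 674, 631, 0.670, 0.684, 0.677, 0.377),
    (1848, 1264, 876, 204, 0.678, 0.901, 0.774, 0.515),
    (1216, 1713, 434, 829, 0.737, 0.595, 0.658, 0.402),
    (1212, 1711, 438, 831, 0.735, 0.593, 0.656, 0.398),
]


class TestParseDotbracket:
    def test_pairs_both_directions(self):
        pairs = parse_dotbracket("([)]")
        assert pairs == {1: 3, 3: 1, 2: 4, 4: 2}

    def test_unbalanced_close(self):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_dotbracket("..)..")

    def test_unbalanced_open(self):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_dotbracket("([.]")

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="invalid"):
            parse_dotbracket(".{.}")


class TestConfusion:
    def test_identity_on_worked_structure(self):
        c = confusion(WORKED_FINAL_DB, WORKED_FINAL_DB)
        assert (c.tp, c.tn, c.fp, c.fn) == (12, 7, 0, 0)

    def test_all_dots_prediction(self):
        c = confusion("." * 19, WORKED_FINAL_DB)
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 12, 7, 0)

    def test_identical_means_no_errors(self):
        c = confusion("..((..))..", "..((..))..")
        assert c.fp == 0 and c.fn == 0

    def test_total_equals_length(self):
        c = confusion("." * 19, WORKED_FINAL_DB)
        assert c.total == 19

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion("...", "....")

    def test_strict_partner_mode(self):
        # both paired everywhere, but partners differ at all four positions
        c_loose = confusion("(())", "()()")
        c_strict = confusion("(())", "()()", strict_partners=True)
        assert c_loose.tp == 4
        assert c_strict.tp == 0 and c_strict.fp == 4
        assert c_strict.total == 4  # classification stays per-base


class TestScore:
    @pytest.mark.parametrize("tp,tn,fp,fn,ppv,rec,f1,mcc", REFERENCE_ROWS)
    def test_reproduces_reference_tables(self, tp, tn, fp, fn, ppv, rec, f1, mcc):
        m = score(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert round3(m.ppv) == ppv
        assert round3(m.recall) == rec
        assert round3(m.f1) == f1
        assert round3(m.mcc) == mcc

    def test_perfect_counts(self):
        m = score(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
        assert (m.ppv, m.recall, m.f1, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominators_flagged(self):
        m = score(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.ppv == 0.0 and m.recall == 0.0 and m.f1 == 0.0 and m.mcc == 0.0
        assert set(m.degenerate) == {"ppv", "recall", "f1", "mcc"}

    @given(st.integers(1, 5000), st.integers(1, 5000),
           st.integers(0, 5000), st.integers(0, 5000))
    @settings(max_examples=200, deadline=None)
    def test_f1_is_harmonic_mean(self, tp, tn, fp, fn):
        m = score(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        if m.ppv > 0 and m.recall > 0:
            assert m.f1 == pytest.approx(
                2 / (1 / m.ppv + 1 / m.recall))

    @given(st.integers(0, 5000), st.integers(0, 5000),
           st.integers(0, 5000), st.integers(0, 5000))
    @settings(max_examples=200, deadline=None)
    def test_mcc_symmetry(self, tp, tn, fp, fn):
        a = score(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)).mcc
        b = score(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp)).mcc
        assert a == pytest.approx(b)

    def test_metric_ranges(self):
        m = score(ConfusionCounts(tp=10, tn=3, fp=2, fn=7))
        assert 0 <= m.ppv <= 1 and 0 <= m.recall <= 1 and 0 <= m.f1 <= 1
        assert -1 <= m.mcc <= 1


def _cand(i1, j1, i2, j2):
    return PseudoknotCandidate(i1=i1, i2=i2, j1=j1, j2=j2, rule_id=0)


class TestCoreStemMatch:
    def test_identity(self):
        p = _cand(5, 10, 9, 16)
        assert core_stem_match(p, p, slip=1)

    def test_one_position_slippage_each_pair(self):
        pred = _cand(5, 10, 9, 16)
        ref = _cand(4, 10, 9, 17)
        assert core_stem_match(pred, ref, slip=1)

    def test_shift_of_two_fails(self):
        pred = _cand(5, 10, 9, 16)
        ref = _cand(7, 10, 9, 16)
        assert not core_stem_match(pred, ref, slip=1)

    def test_both_coordinates_shifted_fails(self):
        pred = _cand(5, 10, 9, 16)
        ref = _cand(4, 11, 9, 16)  # stem 1 shifted in i AND j
        assert not core_stem_match(pred, ref, slip=1)

    def test_slip_zero_is_exact(self):
        pred = _cand(5, 10, 9, 16)
        ref = _cand(4, 10, 9, 16)
        assert not core_stem_match(pred, ref, slip=0)

    def test_negative_slip_rejected(self):
        p = _cand(5, 10, 9, 16)
        with pytest.raises(ValueError):
            core_stem_match(p, p, slip=-1)


class TestEvaluateDataset:
    def test_single_perfect_prediction(self):
        rec = EvalRecord("a", 19, WORKED_FINAL_DB, WORKED_FINAL_DB,
                         pred_core=_cand(5, 10, 9, 16),
                         ref_core=_cand(5, 10, 9, 16))
        report = evaluate_dataset([rec])
        row = report.overall.iloc[0]
        assert row.exact_matches == 1
        assert row.exact_matches_pct == 100.0
        assert row.f1 == 1.0

    def test_counts_sum_before_metrics(self):
        r1 = EvalRecord("a", 19, WORKED_FINAL_DB, WORKED_FINAL_DB)
        r2 = EvalRecord("b", 19, "." * 19, WORKED_FINAL_DB)
        report = evaluate_dataset([r1, r2])
        row = report.overall.iloc[0]
        # summed counts: tp=12, tn=14, fp=0, fn=12
        assert (row.tp, row.tn, row.fp, row.fn) == (12, 14, 0, 12)
        m = score(ConfusionCounts(tp=12, tn=14, fp=0, fn=12))
        assert row.f1 == round3(m.f1)

    def test_bin_edges_closed_left(self):
        r = EvalRecord("edge", 30, "." * 30, "." * 30)
        report = evaluate_dataset([r], length_bins=(30, 40, 50))
        assert report.per_bin.iloc[0]["bin"] == "30 <= L < 40"

    def test_below_first_edge(self):
        r = EvalRecord("small", 19, "." * 19, "." * 19)
        report = evaluate_dataset([r])
        assert report.per_bin.iloc[0]["bin"] == "L < 30"

    def test_missing_reference_skipped(self):
        r = EvalRecord("gone", 19, "." * 19, "")
        report = evaluate_dataset([r])
        assert report.skipped == ["gone"]
        assert report.overall.empty


def test_round3_half_up():
    assert round3(0.8065) == 0.807
    assert round3(0.0005) == 0.001
    assert round3(0.5934) == 0.593
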