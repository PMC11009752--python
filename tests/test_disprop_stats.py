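"""Reporting odds ratio: point estimate, Wald CI, signal rule, stratification."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import (
    ComparatorDesign, DegenerateTableError, ReportSet, RorResult, TwoByTwo,
    build_contingency, is_signal, ror, round_half_up, stratified_rors,
)
from pvsignal.report_model import DrugMention, DrugRole, Sex

from conftest import make_report

cells = st.integers(min_value=1, max_value=500)


class TestRor:
    @pytest.mark.parametrize("a, n_target, expected", [
        (188, 1254, (1.60, 1.36, 1.89)),    # aclidinium vs tiotropium
        (376, 1883, (2.26, 1.99, 2.57)),    # glycopyrronium vs tiotropium
        (459, 2599, (1.95, 1.73, 2.19)),    # umeclidinium vs tiotropium
    ])
    def test_published_lama_contrasts(self, a, n_target, expected):
        """Published cohort counts reproduce the published ROR and CI."""
        res = ror(TwoByTwo(a, n_target - a, 1238, 12472 - 1238))
        got = tuple(round_half_up(x) for x in (res.ror, res.ci_lower, res.ci_upper))
        assert got == expected
        assert res.is_signal

    def test_unit_table_is_null_and_symmetric(self):
        res = ror(TwoByTwo(1, 1, 1, 1))
        assert res.ror == pytest.approx(1.0)
        assert res.ci_lower * res.ci_upper == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        # hand-computed on cells (0.5, 10.5, 5.5, 100.5)
        res = ror(TwoByTwo(0, 10, 5, 100), correction="haldane_half")
        assert res.correction_applied
        assert res.ror == pytest.approx(0.8701298701298701, rel=1e-12)
        assert res.ci_lower == pytest.approx(0.04490808866651865, rel=1e-9)
        assert res.ci_upper == pytest.approx(16.85945702375665, rel=1e-9)
        assert res.n_cases == 0  # uncorrected count

    def test_haldane_not_applied_without_zero_cell(self):
        assert not ror(TwoByTwo(1, 10, 5, 100), correction="haldane_half").correction_applied

    def test_zero_cell_without_correction_names_the_cell(self):
        with pytest.raises(DegenerateTableError, match="a"):
            ror(TwoByTwo(0, 10, 5, 100))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 1, 1, 1)

    def test_against_independent_implementation(self):
        """Cross-check log-OR and its SE against statsmodels."""
        sm = pytest.importorskip("statsmodels.api")
        for table in [(188, 1066, 1238, 11234), (3, 7, 11, 13), (40, 2, 9, 77)]:
            t = sm.stats.Table2x2([[table[0], table[1]], [table[2], table[3]]])
            res = ror(TwoByTwo(*table))
            assert math.log(res.ror) == pytest.approx(t.log_oddsratio, abs=1e-12)
            width = math.log(res.ci_upper) - math.log(res.ror)
            assert width / 1.959964 == pytest.approx(t.log_oddsratio_se, abs=1e-12)


class TestSignalRule:
    def _result(self, ci_lower, n_cases):
        return RorResult(ror=ci_lower * 1.2, ci_lower=ci_lower,
                         ci_upper=ci_lower * 2, n_cases=n_cases,
                         is_signal=False)

    def test_lower_bound_above_one_with_three_cases(self):
        assert is_signal(self._result(1.05, 3))

    def test_two_cases_never_signal(self):
        assert not is_signal(self._result(1.05, 2))

    def test_lower_bound_exactly_one_is_not_a_signal(self):
        assert not is_signal(self._result(1.0, 50))


class TestProperties:
    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetry_under_cohort_swap(self, a, b, c, d):
        fwd, rev = ror(TwoByTwo(a, b, c, d)), ror(TwoByTwo(c, d, a, b))
        assert fwd.ror * rev.ror == pytest.approx(1.0, rel=1e-12)
        assert fwd.ci_lower * rev.ci_upper == pytest.approx(1.0, rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(derandomize=True, max_examples=100)
    def test_transposition_identity(self, a, b, c, d):
        # the odds ratio is the cross product a*d/(b*c) however factored
        assert ror(TwoByTwo(a, b, c, d)).ror == \
            pytest.approx((a / c) / (b / d), rel=1e-12)

    @given(a=st.integers(1, 200), b=cells, c=cells, d=cells)
    @settings(derandomize=True, max_examples=100)
    def test_strictly_increasing_in_a(self, a, b, c, d):
        assert ror(TwoByTwo(a + 1, b, c, d)).ror > ror(TwoByTwo(a, b, c, d)).ror


def _reports(spec):
    """spec: list of (drug, has_event, sex) -> one-product reports."""
    out = []
    for i, (drug, has_event, sex) in enumerate(spec):
        out.append(make_report(
            f"R{i}", drug=drug, sex=sex,
            events=("ATRIAL FIBRILLATION",) if has_event else ("HEADACHE",)))
    return ReportSet(out)


class TestBuildContingency:
    DESIGN = ComparatorDesign(frozenset({"umeclidinium"}),
                              frozenset({"tiotropium"}))

    def test_four_report_square(self, vocab):
        rs = _reports([("umeclidinium", True, Sex.F), ("umeclidinium", False, Sex.F),
                       ("tiotropium", True, Sex.M), ("tiotropium", False, Sex.M)])
        assert build_contingency(rs, vocab.drugs, vocab, self.DESIGN,
                                 "cardiac_disorders") == TwoByTwo(1, 1, 1, 1)

    def test_multiple_cardiac_terms_count_once(self, vocab):
        rep = make_report("R0", drug="umeclidinium", events=(
            "ATRIAL FIBRILLATION", "CARDIAC FAILURE", "MYOCARDIAL INFARCTION"))
        t = build_contingency(ReportSet([rep]), vocab.drugs, vocab,
                              self.DESIGN, "cardiac_disorders")
        assert t.a == 1

    def test_dual_exposed_report_dropped_when_exclusive(self, vocab):
        rep = make_report("R0")
        rep = rep.__class__(**{**rep.__dict__, "drugs": (
            DrugMention("umeclidinium", DrugRole.PRIMARY_SUSPECT),
            DrugMention("tiotropium", DrugRole.SECONDARY_SUSPECT))})
        t = build_contingency(ReportSet([rep]), vocab.drugs, vocab,
                              self.DESIGN, "cardiac_disorders")
        assert (t.n_target, t.n_comparator) == (0, 0)

    def test_rest_of_database_comparator(self, vocab):
        rs = _reports([("umeclidinium", True, Sex.F), ("tiotropium", False, Sex.F),
                       ("aclidinium", True, Sex.F)])
        design = ComparatorDesign(frozenset({"umeclidinium"}), None)
        t = build_contingency(rs, vocab.drugs, vocab, design, "cardiac_disorders")
        assert t == TwoByTwo(1, 0, 1, 1)

    def test_unknown_group_raises(self, vocab):
        with pytest.raises(KeyError):
            build_contingency(ReportSet([]), vocab.drugs, vocab,
                              self.DESIGN, "nope")


class TestStratified:
    DESIGN = TestBuildContingency.DESIGN

    def test_single_stratum_equals_crude(self, vocab):
        rs = _reports([("umeclidinium", True, Sex.F)] * 3
                      + [("umeclidinium", False, Sex.F)] * 2
                      + [("tiotropium", True, Sex.F)] * 2
                      + [("tiotropium", False, Sex.F)] * 4)
        crude = ror(build_contingency(rs, vocab.drugs, vocab, self.DESIGN,
                                      "cardiac_disorders"))
        per = stratified_rors(rs, vocab.drugs, vocab, self.DESIGN,
                              "cardiac_disorders", "sex")
        assert set(per) == {"F"}
        assert per["F"].result.ror == pytest.approx(crude.ror)

    def test_balanced_strata_are_null(self, vocab):
        rs = _reports([(d, e, s) for s in (Sex.F, Sex.M)
                       for d in ("umeclidinium", "tiotropium")
                       for e in (True, False)])
        per = stratified_rors(rs, vocab.drugs, vocab, self.DESIGN,
                              "cardiac_disorders", "sex")
        assert {k: v.result.ror for k, v in per.items()} == \
            pytest.approx({"F": 1.0, "M": 1.0})

    def test_unbalanced_strata_match_hand_tables(self, vocab):
        rs = _reports(
            [("umeclidinium", True, Sex.F)] * 4 + [("umeclidinium", False, Sex.F)] * 6
            + [("tiotropium", True, Sex.F)] * 2 + [("tiotropium", False, Sex.F)] * 8
            + [("umeclidinium", True, Sex.M)] * 1 + [("umeclidinium", False, Sex.M)] * 9
            + [("tiotropium", True, Sex.M)] * 5 + [("tiotropium", False, Sex.M)] * 5)
        per = stratified_rors(rs, vocab.drugs, vocab, self.DESIGN,
                              "cardiac_disorders", "sex")
        assert per["F"].result.ror == pytest.approx((4 / 6) / (2 / 8))
        assert per["M"].result.ror == pytest.approx((1 / 9) / (5 / 5))

    def test_zero_cell_stratum_reported_degenerate(self, vocab):
        rs = _reports([("umeclidinium", True, Sex.F), ("tiotropium", False, Sex.F)])
        per = stratified_rors(rs, vocab.drugs, vocab, self.DESIGN,
                              "cardiac_disorders", "sex")
        assert per["F"].result is None
        assert per["F"].table == TwoByTwo(1, 0, 0, 1)
        assert "zero cell" in per["F"].reason
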