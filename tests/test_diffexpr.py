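"""The exact two-library count test, fold changes, classification and summaries.

The independent oracle for the test statistic is exact rational arithmetic
(`fractions.Fraction` with the direct factorial formula); a second
independent route is the negative-binomial identity: p(y|x) is the
NB(x+1, N1/(N1+N2)) pmf at y.  The implementation under test uses neither
(it evaluates in log space via log-gamma).
"""

import math
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spikefill.diffexpr import (
    DERecord,
    ac_probability,
    ac_pvalue,
    benjamini_hochberg,
    classify_de,
    log2_fold_change,
    paired_ttest,
    stage_comparison,
    summarize_de,
)
from spikefill.normalization import abundance_filter, apply_floor, tpm_normalize
from spikefill.simulate import SimulationConfig, simulate_counts


def oracle_probability(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact rational evaluation of the closed-form statistic."""
    r = Fraction(n2, n1)
    return r**y * Fraction(factorial(x + y), factorial(x) * factorial(y)) / (1 + r) ** (x + y + 1)


class TestAcProbability:
    def test_zero_zero_equal_totals_is_half(self):
        assert ac_probability(0, 0, 10**6, 10**6) == pytest.approx(0.5, rel=1e-12)

    def test_small_closed_form(self):
        # 3!/(2! 1!) * 2^-4 = 3/16
        assert ac_probability(2, 1, 10**6, 10**6) == pytest.approx(3 / 16, rel=1e-12)

    def test_unequal_totals_against_exact_rational(self):
        got = ac_probability(10, 30, 10**6, 2 * 10**6)
        want = float(oracle_probability(10, 30, 10**6, 2 * 10**6))
        assert got == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(0.024954587006106706, rel=1e-12)

    @given(
        x=st.integers(min_value=0, max_value=100),
        y=st.integers(min_value=0, max_value=100),
        n1=st.sampled_from([10**4, 10**6, 2 * 10**6]),
        n2=st.sampled_from([10**4, 10**6, 2 * 10**6]),
    )
    @settings(max_examples=150, deadline=None)
    def test_log_gamma_matches_rational_oracle(self, x, y, n1, n2):
        got = ac_probability(x, y, n1, n2)
        want = float(oracle_probability(x, y, n1, n2))
        assert got == pytest.approx(want, rel=1e-10)

    def test_negative_binomial_identity(self):
        # independent route: p(y|x) = NB(x+1, N1/(N1+N2)).pmf(y)
        n1, n2 = 10**6, 2 * 10**6
        for x, y in [(0, 0), (5, 2), (40, 80), (100, 33)]:
            want = stats.nbinom.pmf(y, x + 1, n1 / (n1 + n2))
            assert ac_probability(x, y, n1, n2) == pytest.approx(want, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ac_probability(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            ac_probability(0, 0, 0, 10)

    def test_distribution_sums_to_one(self):
        for x, n1, n2 in [(0, 10**6, 10**6), (7, 10**4, 2 * 10**6), (50, 2 * 10**6, 10**4)]:
            # p_lower telescopes the whole sum; truncate 40 sd past the mean
            r = n2 / n1
            mu = (x + 1) * r
            sd = math.sqrt((x + 1) * r * (1 + r))
            p_lower, _, _ = ac_pvalue(x, int(mu + 40 * sd) + 1, n1, n2)
            assert p_lower == pytest.approx(1.0, abs=1e-9)


class TestAcPvalue:
    def test_single_term_lower_tail(self):
        p_lower, p_upper, p_two = ac_pvalue(5, 0, 10**6, 10**6)
        assert p_lower == pytest.approx(2**-6, rel=1e-12)
        assert p_upper == 1.0
        assert p_two == pytest.approx(2**-5, rel=1e-12)

    def test_tails_overlap_at_observed_point(self):
        for x, y in [(3, 9), (20, 10), (0, 0)]:
            p_lower, p_upper, _ = ac_pvalue(x, y, 10**6, 3 * 10**6)
            point = ac_probability(x, y, 10**6, 3 * 10**6)
            assert p_lower + p_upper == pytest.approx(1.0 + point, abs=1e-9)

    def test_symmetry_under_swap_with_equal_totals(self):
        # the pmf is symmetric pointwise: p(y|x) = p(x|y) when N1 = N2.
        # (Tail sums are NOT swap-symmetric in general — they sum over
        # different variables — so only x = y gives a symmetric two-sided p.)
        for x, y in [(4, 9), (30, 12)]:
            assert ac_probability(x, y, 10**6, 10**6) == pytest.approx(
                ac_probability(y, x, 10**6, 10**6), rel=1e-12
            )
        for x in (0, 1, 17):
            p_lower, p_upper, p_two = ac_pvalue(x, x, 10**6, 10**6)
            assert p_two >= ac_probability(x, x, 10**6, 10**6)
            assert p_two > 0.9  # observed point sits near the centre

    def test_upper_tail_monotone_in_y(self):
        ups = [ac_pvalue(10, y, 10**6, 2 * 10**6)[1] for y in range(0, 120)]
        assert all(b <= a + 1e-12 for a, b in zip(ups, ups[1:]))


class TestFoldChange:
    @pytest.mark.parametrize(
        "inf,sup,ratio,fc",
        [
            (20.0, 10.0, 2.0, 1.0),
            (10.0, 10.0, 1.0, 0.0),
            (0.0, 10.0, 0.001, math.log2(0.001)),  # floored: ~ -9.966
            (10.0, 0.0, 1000.0, math.log2(1000.0)),
        ],
    )
    def test_examples(self, inf, sup, ratio, fc):
        r, got = log2_fold_change(inf, sup)
        assert r == pytest.approx(ratio, rel=1e-12)
        assert got == pytest.approx(fc, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 2.0)


class TestClassify:
    @pytest.mark.parametrize(
        "fc,p,label",
        [
            (1.5, 0.03, "differential"),
            (-2.0, 0.004, "significant"),
            (0.5, 0.001, "not_de"),   # fold-change gate fails
            (1.5, 0.01, "differential"),  # boundary belongs to differential
            (1.5, 0.05, "differential"),
            (1.5, 0.051, "not_de"),
            (1.0, 0.001, "not_de"),   # |fc| gate is strict
        ],
    )
    def test_rule(self, fc, p, label):
        assert classify_de(fc, p) == label


class TestPairedTTest:
    def test_frozen_example(self):
        # differences [1,2,3,1,2]: t = 1.8 / (sqrt(0.7)/sqrt(5))
        res = paired_ttest([2, 4, 6, 3, 5], [1, 2, 3, 2, 3])
        assert res.n_pairs == 5
        assert res.t_statistic == pytest.approx(4.81070235, rel=1e-6)
        assert res.p_value == pytest.approx(0.00858092, rel=1e-4)
        assert res.direction == "superior_higher"

    def test_identical_series(self):
        res = paired_ttest([1, 2, 3], [1, 2, 3])
        assert (res.t_statistic, res.p_value, res.direction) == (0.0, 1.0, "none")

    def test_constant_nonzero_difference_flagged(self):
        res = paired_ttest([2, 3, 4], [1, 2, 3])
        assert res.p_value == 0.0 and res.degenerate
        assert res.direction == "superior_higher"

    def test_uniform_shift_with_jitter(self, rng):
        sup = np.arange(5) + 10.0 + rng.normal(0, 0.01, 5)
        res = paired_ttest(sup, np.arange(5, dtype=float))
        assert res.direction == "superior_higher"

    def test_too_short(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])


class TestStageComparison:
    def test_identical_counts_equal_totals_not_de(self, design_meta):
        import pandas as pd
        counts = pd.DataFrame(
            {m.library_id: [500] for m in design_meta},
            index=pd.Index(["mirX"], name="entity_id"), dtype="int64",
        )
        # equalize totals so the comparison is exactly symmetric
        from spikefill.io import LibraryMeta
        meta = [LibraryMeta(m.library_id, m.condition, m.stage_daf, 10**6) for m in design_meta]
        expr = apply_floor(tpm_normalize(counts, meta))
        recs = stage_comparison(expr, meta, counts)
        assert len(recs) == 5
        for r in recs:
            assert r.log2_fc == pytest.approx(0.0) and r.label == "not_de"

    def test_spiked_effects_recovered(self):
        cfg = SimulationConfig(seed=11, n_mirnas=80, de_fraction=0.25,
                               de_log2fc_range=(2.0, 2.0), dispersion=0.0,
                               baseline_log_tpm_mean=5.5)
        counts, meta, truth = simulate_counts(cfg)
        expr = apply_floor(tpm_normalize(counts, meta))
        kept, _ = abundance_filter(expr)
        recs = stage_comparison(kept, meta, counts)
        spiked = {e for e, fc in truth.de_log2fc.items() if e in kept.index}
        hits = 0
        for e in spiked:
            labels = [r.label for r in recs if r.entity_id == e]
            hits += any(l != "not_de" for l in labels)
        assert hits / len(spiked) > 0.9


class TestSummarize:
    @staticmethod
    def _rec(entity, stage, fc, label):
        return DERecord(entity, stage, 10.0, 10.0 * 2**fc, 2.0**fc, fc,
                        0.001, 0.5, 0.002, label)

    def test_printed_percentages(self):
        # 109 DE records at one stage, 103 with fc < 0 (higher in superior)
        records = [self._rec(f"m{i}", 15, -2.0, "significant") for i in range(103)]
        records += [self._rec(f"p{i}", 15, 2.0, "significant") for i in range(6)]
        summary = summarize_de(records, [])
        st15 = summary["per_stage"][15]
        assert st15["n_de"] == 109
        assert st15["pct_higher_superior"] == 94.50
        assert st15["pct_higher_inferior"] == 5.50

    def test_paired_direction_percentages(self):
        from spikefill.diffexpr import PairedTestResult
        tests = (
            [PairedTestResult(f"s{i}", 5, 3.0, 0.01, "superior_higher") for i in range(19)]
            + [PairedTestResult(f"i{i}", 5, -3.0, 0.01, "inferior_higher") for i in range(11)]
            + [PairedTestResult(f"n{i}", 5, 0.5, 0.6, "none") for i in range(130)]
        )
        summary = summarize_de([], tests)
        assert summary["paired"]["pct_consistently_superior"] == 11.88
        assert summary["paired"]["pct_consistently_inferior"] == 6.88

    def test_empty_records(self):
        summary = summarize_de([], [])
        assert summary["per_stage"] == {} and summary["n_de_any_stage"] == 0
        assert summary["paired"]["pct_consistently_superior"] == 0.0


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.004)
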