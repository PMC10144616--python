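import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from pvaff import (
    ContingencyTable,
    build_contingency,
    evaluate_drug,
    fisher_p,
    reporting_ratio,
    ror_with_ci,
    screen_signals,
    volcano_coordinates,
)

counts = st.integers(min_value=0, max_value=60)


def enumerate_fisher(a, b, c, d, sidedness):
    """Exact-rational hypergeometric enumeration (independent oracle)."""
    N, r, cm = a + b + c + d, a + b, a + c
    if min(r, cm, N - r, N - cm) == 0:
        return 1.0
    lo, hi = max(0, r + cm - N), min(r, cm)
    denom = math.comb(N, r)
    pmf = {k: Fraction(math.comb(cm, k) * math.comb(N - cm, r - k), denom)
           for k in range(lo, hi + 1)}
    if sidedness == "right_tailed":
        return float(sum(p for k, p in pmf.items() if k >= a))
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


class TestRorWithCi:
    def test_balanced_table_is_unity(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(1, 1, 1, 1))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_large_cohort_table(self):
        # 665 event reports among 4602 for the drug vs 1214 among ~2.03M
        t = ContingencyTable(665, 3937, 1879 - 665, 2037648 - 3937)
        ror, lo, hi = ror_with_ci(t)
        assert round(ror, 2) == 283.02
        assert (round(lo, 2), round(hi, 2)) == (256.20, 312.65)

    def test_zero_cell_stays_finite(self):
        t = ContingencyTable(0, 1810, 1879, 2037648 - 1810)
        ror, lo, hi = ror_with_ci(t)
        assert round(ror, 2) == 0.30
        assert round(hi, 2) == 4.79

    @given(counts, counts, counts, counts)
    def test_transpose_invariance_and_exposure_inversion(self, a, b, c, d):
        ror, _, _ = ror_with_ci(ContingencyTable(a, b, c, d))
        ror_t, _, _ = ror_with_ci(ContingencyTable(a, c, b, d))
        inv, _, _ = ror_with_ci(ContingencyTable(b, a, d, c))
        assert ror == pytest.approx(ror_t, rel=1e-12)
        assert inv == pytest.approx(1.0 / ror, rel=1e-12)

    def test_ci_width_shrinks_with_scale(self):
        widths = []
        for k in (1, 10, 100):
            ror, lo, hi = ror_with_ci(ContingencyTable(2 * k, 8 * k, 5 * k, 85 * k))
            widths.append(math.log(hi) - math.log(lo))
        assert widths[0] > widths[1] > widths[2]


class TestFisherP:
    def test_balanced_table_p_is_one(self):
        assert fisher_p(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        ContingencyTable(0, 0, 3, 4),
        ContingencyTable(0, 5, 0, 4),
        ContingencyTable(0, 0, 0, 0),
    ])
    def test_zero_margin_gives_one(self, table):
        assert fisher_p(table) == 1.0
        assert fisher_p(table, "right_tailed") == 1.0

    @pytest.mark.parametrize("cells", [(2, 3, 4, 5), (1, 9, 11, 3),
                                       (0, 12, 8, 2), (7, 0, 1, 6)])
    @pytest.mark.parametrize("side", ["two_sided", "right_tailed"])
    def test_matches_exact_enumeration(self, cells, side):
        got = fisher_p(ContingencyTable(*cells), side)
        want = enumerate_fisher(*cells, side)
        assert got == pytest.approx(want, rel=1e-9)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_agrees_with_scipy_fisher_exact(self, a, b, c, d):
        mine = fisher_p(ContingencyTable(a, b, c, d))
        ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_enriched_direction_right_tail_below_two_sided(self):
        t = ContingencyTable(9, 1, 2, 8)
        assert fisher_p(t, "right_tailed") < fisher_p(t, "two_sided")

    def test_huge_margins_stay_exact(self):
        t = ContingencyTable(665, 3937, 1879 - 665, 2037648 - 3937)
        assert fisher_p(t) < 0.001
        assert 0.0 <= fisher_p(t, "right_tailed") < 0.001


class TestReportingRatio:
    @pytest.mark.parametrize("a,b,expected_pct", [
        (10, 70, 12.5),
        (0, 5, 0.0),
        (344, 2222, 13.4),  # one-decimal display convention
    ])
    def test_fraction_of_drug_reports(self, a, b, expected_pct):
        got = reporting_ratio(ContingencyTable(a, b, 1, 1))
        assert round(100 * got, 1) == pytest.approx(expected_pct)

    def test_no_reports_is_missing(self):
        assert math.isnan(reporting_ratio(ContingencyTable(0, 0, 3, 4)))


class TestBuildContingency:
    def test_toy_counts(self, tiny_records):
        t = build_contingency(tiny_records, "drug X", "atypical femoral fracture")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)
        assert t.n == len(tiny_records)

    def test_unreported_drug_degenerate(self, tiny_records):
        t = build_contingency(tiny_records, "ghost", "atypical femoral fracture")
        assert (t.a, t.b) == (0, 0)


class TestScreenAndVolcano:
    @pytest.mark.parametrize("ror,p,expected", [
        (2.0, 0.01, True),
        (0.9, 0.001, False),
        (1.0, 0.05, True),   # inclusive bounds
        (2.0, 0.051, False),
    ])
    def test_signal_rule(self, ror, p, expected, tiny_records):
        t = ContingencyTable(2, 2, 1, 5)
        base = evaluate_drug("x", t)
        forced = type(base)(**{**base.__dict__, "ror": ror, "p_two_sided": p})
        flagged = screen_signals([forced])
        assert (len(flagged) == 1) is expected

    def test_signals_sorted_by_descending_ror(self, tiny_records):
        res = [evaluate_drug("x", ContingencyTable(5, 5, 1, 89)),
               evaluate_drug("y", ContingencyTable(9, 1, 1, 89))]
        sigs = screen_signals(res)
        rors = [r.ror for r in sigs]
        assert rors == sorted(rors, reverse=True)

    def test_volcano_origin_and_unit_points(self):
        t = ContingencyTable(1, 1, 1, 1)
        r = evaluate_drug("o", t)
        forced = type(r)(**{**r.__dict__, "ror": 1.0, "p_two_sided": 1.0,
                            "ln_ror": 0.0, "neg_log10_p": 0.0})
        unit = type(r)(**{**r.__dict__, "ror": math.e, "p_two_sided": 0.1,
                          "ln_ror": 1.0, "neg_log10_p": 1.0})
        (x0, y0, _), (x1, y1, _) = volcano_coordinates([forced, unit])
        assert (x0, y0) == (0.0, 0.0)
        assert (x1, y1) == (1.0, 1.0)
        # axis assignment configurable
        (sx, sy, _), _ = volcano_coordinates([forced, unit], p_axis="y")
        assert (sx, sy) == (y0, x0)

    def test_ci_coverage_of_planted_odds_ratio(self):
        # replicate 2x2 sampling with true odds ratio 3 and check ~95% coverage
        rng = np.random.default_rng(2023)
        omega, n_exp, n_unexp = 3.0, 4000, 16000
        p0 = 0.02
        p1 = omega * p0 / (1 - p0 + omega * p0)
        hits = 0
        reps = 400
        for _ in range(reps):
            a = rng.binomial(n_exp, p1)
            c = rng.binomial(n_unexp, p0)
            _, lo, hi = ror_with_ci(
                ContingencyTable(a, n_exp - a, c, n_unexp - c))
            hits += lo <= omega <= hi
        assert 0.90 <= hits / reps <= 0.985
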