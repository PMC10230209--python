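import numpy as np
import pytest
from scipy import optimize, stats

from hashlink.validate import (
    CrossTab2x2,
    binary_roc_auc,
    build_report,
    cross_tabulate,
    exact_binomial_ci,
    format_percent,
    pearson_chi2,
    sensitivity_specificity,
)


def _ci_by_tail_inversion(s, n, level=0.95):
    """Independent Clopper–Pearson oracle: bracket the roots of the
    defining binomial tail equations with brentq on the binomial CDF."""
    alpha = 1 - level
    if s == 0:
        lower = 0.0
    else:
        lower = optimize.brentq(
            lambda p: (1 - stats.binom.cdf(s - 1, n, p)) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-13,
        )
    if s == n:
        upper = 1.0
    else:
        upper = optimize.brentq(
            lambda p: stats.binom.cdf(s, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-13
        )
    return lower, upper


class TestCrossTabulate:
    def test_counts_each_record_once(self):
        gold = [True, True, False, False, True]
        hashk = [True, True, True, False, True]
        t = cross_tabulate(gold, hashk)
        assert (t.a, t.b, t.c, t.d) == (3, 1, 0, 1)
        assert t.n == 5

    def test_all_unique_both_keys(self):
        t = cross_tabulate([True] * 4, [True] * 4)
        assert (t.a, t.b, t.c, t.d) == (4, 0, 0, 0)

    def test_mismatched_records_hard_error(self):
        with pytest.raises(ValueError, match="different record sets"):
            cross_tabulate([True], [True, False])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CrossTab2x2(-1, 0, 0, 0)


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "cells, sens, spec",
        [
            ((2296, 10, 0, 316), 1.0, 0.969),
            ((6601, 142, 0, 19941), 1.0, 0.993),
            ((5, 0, 0, 7), 1.0, 1.0),
        ],
    )
    def test_point_estimates(self, cells, sens, spec):
        s, p = sensitivity_specificity(CrossTab2x2(*cells))
        assert s == pytest.approx(sens, abs=5e-4)
        assert p == pytest.approx(spec, abs=5e-4)

    def test_empty_margin_is_undefined_not_zero(self):
        s, p = sensitivity_specificity(CrossTab2x2(3, 0, 0, 0))
        assert s == 1.0 and p is None


class TestExactBinomialCI:
    @pytest.mark.parametrize(
        "s, n, lo, hi",
        [
            (2296, 2296, 0.998, 1.0),
            (316, 326, 0.944, 0.985),
            (160, 169, 0.901, 0.975),
            (19941, 20083, 0.992, 0.994),
        ],
    )
    def test_reference_rosters_to_3dp(self, s, n, lo, hi):
        lower, upper = exact_binomial_ci(s, n)
        assert round(lower, 3) == lo and round(upper, 3) == hi

    def test_boundary_closed_forms(self):
        lower, upper = exact_binomial_ci(0, 10)
        assert lower == 0.0
        assert upper == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)
        lower, upper = exact_binomial_ci(10, 10)
        assert upper == 1.0
        assert lower == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    @pytest.mark.parametrize("s, n", [(0, 7), (3, 9), (50, 60), (316, 326), (2296, 2296)])
    def test_tail_inversion_oracle(self, s, n):
        got = exact_binomial_ci(s, n)
        want = _ci_by_tail_inversion(s, n)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_trials_undefined(self):
        assert exact_binomial_ci(0, 0) is None

    def test_wilson_differs_where_expected(self):
        # the Wilson upper bound at 316/326 rounds to 98.3%, not 98.5%
        _, upper = exact_binomial_ci(316, 326, method="wilson")
        assert round(upper, 3) == 0.983


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((2296, 10, 0, 316), 2530.549),
            ((2344, 9, 0, 160), 2370.071),
            ((6601, 142, 0, 19941), 25937.365),
        ],
    )
    def test_reference_statistics_to_3dp(self, cells, expected):
        stat, p = pearson_chi2(CrossTab2x2(*cells))
        assert round(stat, 3) == expected
        assert p < 0.001

    def test_exact_independence_gives_zero(self):
        stat, p = pearson_chi2(CrossTab2x2(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_undefined(self):
        assert pearson_chi2(CrossTab2x2(5, 0, 3, 0)) is None

    def test_expected_count_oracle_and_scipy(self, rng):
        """Closed form agrees with sum((O-E)^2/E) and with
        scipy.stats.chi2_contingency (no continuity correction)."""
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = CrossTab2x2(int(a), int(b), int(c), int(d))
            stat, p = pearson_chi2(t)
            obs = t.as_array()
            exp = np.outer(obs.sum(1), obs.sum(0)) / t.n
            assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-9)
        res = stats.chi2_contingency(CrossTab2x2(23, 41, 7, 311).as_array(), correction=False)
        assert pearson_chi2(CrossTab2x2(23, 41, 7, 311))[0] == pytest.approx(res.statistic, rel=1e-12)


class TestRocAuc:
    @pytest.mark.parametrize(
        "sens, spec, auc", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5), (1.0, 0.969, 0.9845)]
    )
    def test_single_threshold_identity(self, sens, spec, auc):
        assert binary_roc_auc(sens, spec) == pytest.approx(auc, abs=1e-12)

    def test_matches_trapezoid(self):
        sens, spec = 0.8, 0.6
        x = [0.0, 1 - spec, 1.0]
        y = [0.0, sens, 1.0]
        assert binary_roc_auc(sens, spec) == pytest.approx(np.trapezoid(y, x), abs=1e-12)


class TestReportFormatting:
    def test_percent_rounding_half_up(self):
        assert format_percent(0.96933) == "96.9%"
        assert format_percent(1.0) == "100%"
        assert format_percent(0.8765) == "87.7%"  # half-up, not banker's
        assert format_percent(None) == "undefined"

    def test_chi2_rendered_to_3dp(self):
        rep = build_report(CrossTab2x2(2296, 10, 0, 316))
        assert "chi-square: 2530.549, p < 0.001" in rep.summary()

    def test_undefined_statistics_flagged(self):
        rep = build_report(CrossTab2x2(4, 0, 0, 0))
        assert "specificity" in rep.undefined and "chi2" in rep.undefined
        assert "undefined statistics" in rep.summary()


def test_specificity_monotone_in_planted_collisions(rng):
    """Adding a gender-discordant collision record never raises
    specificity and never moves sensitivity off 1."""
    from hashlink.dedup import flag_primaries
    from hashlink.hashing import assign_identifiers
    import pandas as pd

    rows = [("M", f"AB{i:06d}") for i in range(30)] + [("M", "AB000001")] * 5
    prev_spec = None
    for k in range(4):
        df = pd.DataFrame(
            rows + [("F", f"AB{i:06d}") for i in range(k)],
            columns=["gender", "service_number"],
        )
        hashed = assign_identifiers(df)
        t = cross_tabulate(
            flag_primaries(hashed["service_number"]), flag_primaries(hashed["uid"])
        )
        sens, spec = sensitivity_specificity(t)
        assert sens == 1.0
        if prev_spec is not None:
            assert spec <= prev_spec
        prev_spec = spec
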