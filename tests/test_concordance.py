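"""Concordance statistics vs independent brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdl1tps.concordance import (ScoreTable, agreement_at_cutoff,
                                 compare_scores, consolidate_median,
                                 inter_rater_delta, leave_one_out_median,
                                 lin_ccc, mae, pearson,
                                 restricted_concordance)


def _brute_lcc(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx2 = np.mean((x - x.mean()) ** 2)
    sy2 = np.mean((y - y.mean()) ** 2)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)


class TestLinCcc:
    def test_perfect_concordance(self):
        assert lin_ccc([10, 50, 90], [10, 50, 90]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert lin_ccc([-1, 0, 1], [1, 0, -1]) == pytest.approx(-1.0)

    def test_location_shift_penalized_below_pearson(self):
        x, y = [0, 50, 100], [10, 60, 110]
        assert pearson(x, y) == pytest.approx(1.0)
        assert lin_ccc(x, y) < 1.0
        assert lin_ccc(x, y) == pytest.approx(_brute_lcc(x, y))

    def test_constant_input_flagged_nan(self):
        assert np.isnan(lin_ccc([5, 5, 5], [1, 2, 3]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, 20)
        y = np.clip(x + rng.normal(0, 15, 20), 0, 100)
        assert lin_ccc(x, y) == pytest.approx(_brute_lcc(x, y), abs=1e-9)
        assert abs(lin_ccc(x, y)) <= abs(pearson(x, y)) + 1e-9


class TestPearsonMae:
    def test_identity(self):
        x = [0.0, 10.0, 70.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert mae(x, x) == 0.0

    def test_affine_invariance_of_correlation(self):
        x = np.array([0.0, 10.0, 30.0])
        y = 2 * x + 5
        assert pearson(x, y) == pytest.approx(1.0)
        assert mae(x, y) > 0

    def test_mae_example(self):
        assert mae([0, 10], [10, 30]) == pytest.approx(15.0)


class TestAgreementAtCutoff:
    def test_identical_scores_fully_agree(self):
        s = [10.0, 30.0, 60.0, 20.0]
        assert agreement_at_cutoff(s, s) == (1.0, 1.0, 1.0)

    def test_full_discordance(self):
        opa, npa, ppa = agreement_at_cutoff([10, 30], [30, 10])
        assert (opa, npa, ppa) == (0.0, 0.0, 0.0)

    def test_no_reference_negatives_flag_npa(self):
        opa, npa, ppa = agreement_at_cutoff([30, 40], [30, 10])
        assert np.isnan(npa)
        assert ppa == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_contingency(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0, 100, 20)
        test = rng.uniform(0, 100, 20)
        opa, npa, ppa = agreement_at_cutoff(ref, test, 25.0)
        a = b = c = d = 0
        for r, t in zip(ref, test):
            rp, tp_ = r >= 25.0, t >= 25.0
            a += rp and tp_
            b += rp and not tp_
            c += (not rp) and tp_
            d += (not rp) and not tp_
        assert opa == pytest.approx((a + d) / 20)
        if c + d:
            assert npa == pytest.approx(d / (c + d))
        if a + b:
            assert ppa == pytest.approx(a / (a + b))

    def test_reference_is_first_argument(self):
        # 1 ref-positive scored negative by test: PPA penalized, not NPA
        ref, test = [30.0, 10.0], [10.0, 10.0]
        _, npa, ppa = agreement_at_cutoff(ref, test)
        assert (npa, ppa) == (1.0, 0.0)
        _, npa_swapped, ppa_swapped = agreement_at_cutoff(test, ref)
        assert np.isnan(ppa_swapped) or ppa_swapped != ppa or npa_swapped != npa

    def test_all_sixteen_status_patterns_of_four_slides(self):
        """Exhaustive check against the 2x2 contingency on every status
        pattern of a 4-slide table."""
        for bits in range(16):
            ref = [40.0 if bits >> i & 1 else 10.0 for i in range(4)]
            for bits2 in range(16):
                test = [40.0 if bits2 >> i & 1 else 10.0 for i in range(4)]
                opa, npa, ppa = agreement_at_cutoff(ref, test)
                a = sum(r >= 25 and t >= 25 for r, t in zip(ref, test))
                b = sum(r >= 25 and t < 25 for r, t in zip(ref, test))
                c = sum(r < 25 and t >= 25 for r, t in zip(ref, test))
                d = sum(r < 25 and t < 25 for r, t in zip(ref, test))
                assert opa == pytest.approx((a + d) / 4)
                assert np.isnan(npa) if c + d == 0 else npa == pytest.approx(d / (c + d))
                assert np.isnan(ppa) if a + b == 0 else ppa == pytest.approx(a / (a + b))


class TestInterRaterDelta:
    def test_identical_scores_zero(self):
        assert inter_rater_delta([10, 10, 10]) == 0.0

    def test_three_rater_example(self):
        assert inter_rater_delta([0, 30, 60]) == pytest.approx(40.0)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6), st.integers(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant(self, scores, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(scores)
        rng.shuffle(shuffled)
        assert inter_rater_delta(shuffled) == pytest.approx(inter_rater_delta(scores))

    def test_equals_bruteforce_pair_mean(self, rng):
        scores = rng.uniform(0, 100, 5)
        brute = np.mean([abs(a - b) for a, b in combinations(scores, 2)])
        assert inter_rater_delta(scores) == pytest.approx(brute)


class TestConsolidateMedian:
    @pytest.mark.parametrize(
        "scores, expected",
        [((10, 20, 90), 20.0), ((7, 7, 50), 7.0), ((10, 20, 30, 40), 25.0)],
    )
    def test_median_convention(self, scores, expected):
        assert consolidate_median(scores) == expected


def _random_table(rng, n=12, noise=10.0):
    true = rng.uniform(0, 100, n)
    visual = np.clip(true[:, None] + rng.normal(0, noise, (n, 3)), 0, 100)
    auto = np.clip(true + rng.normal(0, 5.0, n), 0, 100)
    return ScoreTable(
        slide_ids=[f"s{i}" for i in range(n)], visual=visual, automated=auto
    )


class TestRestrictedConcordance:
    def test_largest_threshold_reproduces_global_report(self, rng):
        table = _random_table(rng)
        global_report = compare_scores(table.consolidated(), table.automated)
        points = restricted_concordance(table, [table.deltas().max()])
        assert points[0].included_fraction == 1.0
        assert points[0].report.as_dict() == global_report.as_dict()

    def test_threshold_below_min_flagged(self, rng):
        table = _random_table(rng)
        points = restricted_concordance(table, [table.deltas().min() - 1.0])
        assert points[0].report is None
        assert points[0].included_fraction == 0.0

    def test_noise_free_half_selected_at_zero_threshold(self, rng):
        n = 10
        true = rng.uniform(10, 90, n)
        visual = np.repeat(true[:, None], 3, axis=1)
        visual[n // 2 :] += rng.uniform(1, 5, (n - n // 2, 3)) * np.array([1, -1, 0.5])
        visual = np.clip(visual, 0, 100)
        table = ScoreTable(
            slide_ids=[f"s{i}" for i in range(n)],
            visual=visual,
            automated=np.clip(true + 1.0, 0, 100),
        )
        points = restricted_concordance(table, [0.0])
        assert points[0].included_fraction == pytest.approx(0.5)
        expected = compare_scores(true[: n // 2], np.clip(true[: n // 2] + 1.0, 0, 100))
        assert points[0].report.as_dict() == pytest.approx(expected.as_dict(), nan_ok=True)


class TestLeaveOneOutMedian:
    def test_identical_sources_all_perfect(self):
        scores = np.array([[10.0, 10, 10], [40, 40, 40], [80, 80, 80]])
        table = ScoreTable(
            slide_ids=["a", "b", "c"], visual=scores, automated=scores[:, 0].copy()
        )
        reports = leave_one_out_median(table)
        assert len(reports) == 4
        for rep in reports.values():
            assert rep.lcc == pytest.approx(1.0)
            assert rep.mae == 0.0
            assert rep.opa == 1.0

    def test_offset_source_isolated(self):
        base = np.array([10.0, 40.0, 80.0])
        visual = np.stack([base, base, base], axis=1)
        table = ScoreTable(
            slide_ids=["a", "b", "c"], visual=visual, automated=base + 10.0
        )
        reports = leave_one_out_median(table)
        assert reports["automated"].mae == pytest.approx(10.0)
        for name in ("rater_1", "rater_2", "rater_3"):
            assert reports[name].mae == 0.0


class TestScoreTable:
    def test_csv_roundtrip(self, rng, tmp_path):
        table = _random_table(rng)
        table.to_csv(tmp_path / "scores.csv")
        back = ScoreTable.from_csv(tmp_path / "scores.csv")
        assert back.slide_ids == table.slide_ids
        assert np.allclose(back.visual, table.visual)
        assert np.allclose(back.automated, table.automated)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoreTable(slide_ids=["a"], visual=[[10.0, 120.0, 30.0]], automated=[50.0])
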