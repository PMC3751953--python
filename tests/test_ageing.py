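import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishdemog.ageing import (compute_periodicity, summarize_periodicity, iape,
                              percent_agreement, confidence_code_counts,
                              monthly_marginal_increment, monthly_edge_percent,
                              fit_allometry)
from fishdemog.records import FishRecord, ReadingPair
from fishdemog.simulate import OTCRecord

# Per-fish increment-formation periods (days) from the six successfully
# marked fish in the tank validation experiment.
OTC_PERIODS = [370, 309, 371, 326, 344, 358]


def fish(month, age=5, mi=None, edge=None, tl=30.0, **over):
    base = dict(fish_id=over.pop("fish_id", f"f{month}-{age}-{mi}-{edge}"),
                capture_date=datetime.date(2011, month, 15), tl_cm=tl,
                age_yr=age, marginal_increment_mm=mi, edge_type=edge)
    base.update(over)
    return FishRecord(**base)


class TestPeriodicity:
    @pytest.mark.parametrize("x,y,g,expected", [
        (1.0, 1.0, 365, 365.0),     # one full cycle in one year
        (2.0, 1.0, 730, 365.0),     # two cycles in two years
        (1.170, 1.0, 433, 370.09),  # a 1+ zone beyond the mark after 433 d
    ])
    def test_formula(self, x, y, g, expected):
        rec = OTCRecord(fish_id="t", x_mm=x, y_mm=y, g_days=g)
        assert compute_periodicity(rec) == pytest.approx(expected, abs=0.01)

    def test_monotonicity(self):
        base = OTCRecord("t", x_mm=1.2, y_mm=1.0, g_days=400)
        p0 = compute_periodicity(base)
        assert compute_periodicity(OTCRecord("t", 1.5, 1.0, 400)) < p0
        assert compute_periodicity(OTCRecord("t", 1.2, 1.1, 400)) > p0
        assert compute_periodicity(OTCRecord("t", 1.2, 1.0, 500)) > p0

    def test_summary_of_experiment_periods(self):
        summ = summarize_periodicity(OTC_PERIODS)
        assert summ.mean_days == pytest.approx(346.3, abs=0.05)
        assert summ.n == 6
        # both sd conventions exposed; sample sd ~25, population sd ~23
        assert summ.sd_days == pytest.approx(24.97, abs=0.01)
        assert summ.sd_population_days == pytest.approx(22.79, abs=0.01)

    def test_summary_degenerate_and_hand_cases(self):
        constant = summarize_periodicity([365, 365])
        assert (constant.mean_days, constant.sd_days) == (365.0, 0.0)
        two = summarize_periodicity([300, 400])
        assert two.mean_days == 350.0
        assert two.sd_days == pytest.approx(70.71, abs=0.01)

    def test_errors(self):
        with pytest.raises(ValueError):
            summarize_periodicity([])
        with pytest.raises(ValueError):
            OTCRecord("t", x_mm=0.0, y_mm=1.0, g_days=365)


class TestIAPE:
    def test_identical_reads_zero(self):
        pairs = [ReadingPair(str(i), [a, a]) for i, a in enumerate([3, 7, 12])]
        assert iape(pairs) == 0.0

    def test_single_fish_hand_calculation(self):
        # reads 4 and 5: mean 4.5, each |dev|/mean = 0.5/4.5 = 0.111...
        assert iape([ReadingPair("a", [4, 5])]) == pytest.approx(100 / 9, abs=0.005)

    def test_two_fish_average(self):
        pairs = [ReadingPair("a", [10, 10]), ReadingPair("b", [4, 5])]
        assert iape(pairs) == pytest.approx(100 / 18, abs=0.005)

    def test_mean_zero_fish_excluded(self):
        pairs = [ReadingPair("a", [0, 0]), ReadingPair("b", [4, 5])]
        assert iape(pairs) == pytest.approx(100 / 9, abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iape([])

    @given(st.lists(st.lists(st.integers(1, 30), min_size=2, max_size=4),
                    min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_invariances(self, read_sets, rnd):
        """IAPE ignores fish order and read order, and is scale-free."""
        pairs = [ReadingPair(str(i), reads) for i, reads in enumerate(read_sets)]
        baseline = iape(pairs)
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        shuffled = [ReadingPair(p.fish_id, sorted(p.reads, reverse=True))
                    for p in shuffled]
        assert iape(shuffled) == pytest.approx(baseline, rel=1e-12)
        doubled = [ReadingPair(p.fish_id, [2 * r for r in p.reads]) for p in pairs]
        assert iape(doubled) == pytest.approx(baseline, rel=1e-12)


class TestPercentAgreement:
    READS = [(4, 5), (7, 7), (3, 6), (9, 9)]

    def pairs(self):
        return [ReadingPair(str(i), r) for i, r in enumerate(self.READS)]

    def test_identical_full_agreement(self):
        pairs = [ReadingPair(str(i), [a, a]) for i, a in enumerate([2, 5, 9])]
        assert percent_agreement(pairs, 0) == 100.0

    @pytest.mark.parametrize("tol,expected", [(0, 50.0), (1, 75.0), (3, 100.0)])
    def test_tolerance_counts(self, tol, expected):
        assert percent_agreement(self.pairs(), tol) == expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement(self.pairs(), -1)


def test_confidence_code_tabulation():
    pairs = [ReadingPair("a", [4, 4], "G"), ReadingPair("b", [5, 5], "G"),
             ReadingPair("c", [6, 7], "FP"), ReadingPair("d", [3, 3])]
    counts = confidence_code_counts(pairs)
    assert counts["G"] == 2 and counts["FP"] == 1 and counts["P"] == 0


class TestMonthlyMarginalIncrement:
    def test_constant_increments_flat_table(self):
        recs = [fish(m, mi=0.2, fish_id=f"c{m}{i}")
                for m in range(1, 13) for i in range(3)]
        table = monthly_marginal_increment(recs, age_classes={5})
        assert np.allclose(table["mean"], 0.2)
        assert np.allclose(table["sd"].dropna(), 0.0)

    def test_age_class_filter(self):
        recs = ([fish(6, age=5, mi=0.1, fish_id=f"a{i}") for i in range(4)]
                + [fish(6, age=9, mi=0.9, fish_id=f"b{i}") for i in range(4)])
        table = monthly_marginal_increment(recs, age_classes={5, 6})
        assert table.loc[6, "mean"] == pytest.approx(0.1)
        assert table.loc[6, "n"] == 4

    def test_no_usable_records(self):
        with pytest.raises(ValueError):
            monthly_marginal_increment([fish(5, mi=None)], age_classes={5})


class TestMonthlyEdgePercent:
    def test_all_opaque_zero_percent(self):
        recs = [fish(m, edge="opaque", fish_id=f"o{m}{i}")
                for m in (2, 6, 10) for i in range(4)]
        table = monthly_edge_percent(recs)
        assert (table["percent_translucent"].dropna() == 0).all()

    def test_three_of_four_translucent(self):
        recs = ([fish(7, edge="translucent", fish_id=f"t{i}") for i in range(3)]
                + [fish(7, edge="opaque", fish_id="o1")])
        table = monthly_edge_percent(recs)
        assert table.loc[7, "percent_translucent"] == 75.0

    def test_indeterminate_excluded_and_counts_sum(self):
        recs = ([fish(4, edge="translucent", fish_id=f"t{i}") for i in range(2)]
                + [fish(4, edge="opaque", fish_id="o")]
                + [fish(4, edge="indeterminate", fish_id="i")])
        table = monthly_edge_percent(recs)
        assert table.loc[4, "n"] == 3  # indeterminate removed before counting
        assert table.loc[4, "n_translucent"] + table.loc[4, "n_opaque"] == table.loc[4, "n"]
        pct = table["percent_translucent"].dropna()
        assert ((pct >= 0) & (pct <= 100)).all()


def _allometry_sample(rng, n=500, noise_sd=0.0, coefs=None):
    """Records generated from the otolith-weight linear model."""
    if coefs is None:
        coefs = dict(intercept=60.414, age=8.931, spotted=-19.119,
                     female=-19.329, age_spotted=6.111)
    ages = rng.integers(2, 16, size=n)
    spotted = rng.random(n) < 0.5
    female = rng.random(n) < 0.5
    ow = (coefs["intercept"] + coefs["age"] * ages + coefs["spotted"] * spotted
          + coefs["female"] * female + coefs["age_spotted"] * ages * spotted
          + rng.normal(0, noise_sd, n))
    return [FishRecord(fish_id=str(i), capture_date=datetime.date(2011, 6, 1),
                       tl_cm=20.0 + ages[i], sex="female" if female[i] else "male",
                       morph="spotted" if spotted[i] else "plain",
                       oto_weight_mg=float(ow[i]), age_yr=int(ages[i]))
            for i in range(n)]


class TestAllometry:
    def test_noiseless_recovery_exact(self):
        recs = _allometry_sample(np.random.default_rng(1), noise_sd=0.0)
        fit = fit_allometry(recs, response="oto_weight")
        assert fit.params["Intercept"] == pytest.approx(60.414, abs=1e-6)
        assert fit.params["age_yr"] == pytest.approx(8.931, abs=1e-6)
        assert fit.params["spotted"] == pytest.approx(-19.119, abs=1e-6)
        assert fit.params["female"] == pytest.approx(-19.329, abs=1e-6)
        assert fit.params["age_yr:spotted"] == pytest.approx(6.111, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_covers_truth(self):
        """95% CIs catch each generating coefficient in >=90% of replicates."""
        truth = dict(Intercept=60.414, age_yr=8.931, spotted=-19.119,
                     female=-19.329)
        truth["age_yr:spotted"] = 6.111
        hits = {k: 0 for k in truth}
        n_rep = 100
        for rep in range(n_rep):
            recs = _allometry_sample(np.random.default_rng(1000 + rep), noise_sd=5.0)
            fit = fit_allometry(recs, response="oto_weight")
            for name, true_val in truth.items():
                if name not in fit.params.index:
                    continue
                lo = fit.params[name] - 1.96 * fit.bse[name]
                hi = fit.params[name] + 1.96 * fit.bse[name]
                hits[name] += lo <= true_val <= hi
        for name, count in hits.items():
            assert count >= 0.90 * n_rep, (name, count)

    def test_aic_drops_absent_colour_effect(self):
        """With no colour effect in truth, selection discards colour terms."""
        coefs = dict(intercept=60.0, age=9.0, spotted=0.0, female=-19.0,
                     age_spotted=0.0)
        dropped = 0
        n_rep = 50
        for rep in range(n_rep):
            recs = _allometry_sample(np.random.default_rng(2000 + rep),
                                     noise_sd=5.0, coefs=coefs)
            fit = fit_allometry(recs, response="oto_weight")
            dropped += "spotted" not in fit.params.index
        assert dropped >= 0.90 * n_rep

    def test_single_level_factor_rejected(self):
        recs = [r for r in _allometry_sample(np.random.default_rng(3))
                if r.morph == "plain"]
        with pytest.raises(ValueError, match="single level"):
            fit_allometry(recs, response="oto_weight")

    def test_oto_length_response_uses_tl(self):
        rng = np.random.default_rng(4)
        n = 200
        tl = rng.uniform(18, 50, n)
        spotted = rng.random(n) < 0.5
        ol = 0.641 + 0.137 * tl + 0.318 * spotted - 0.021 * tl * spotted
        recs = [FishRecord(fish_id=str(i), capture_date=datetime.date(2011, 6, 1),
                           tl_cm=float(tl[i]), sex="male" if i % 2 else "female",
                           morph="spotted" if spotted[i] else "plain",
                           oto_length_mm=float(ol[i]), age_yr=5)
                for i in range(n)]
        fit = fit_allometry(recs, response="oto_length")
        assert fit.covariate == "tl_cm"
        assert fit.params["tl_cm"] == pytest.approx(0.137, abs=1e-6)
        assert fit.params["tl_cm:spotted"] == pytest.approx(-0.021, abs=1e-6)
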