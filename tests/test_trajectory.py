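"""Lag grouping, time order ratios and the exact binomial test."""

import math
from itertools import product

import pytest

from comorbiscan.cohort import washout_filter
from comorbiscan.synthetic_claims import PlantedPair, SimConfig, generate
from comorbiscan.trajectory import (LAG_GROUPS, binom_two_sided, lag_group,
                                    significance_stars, tor_analysis)


def enumerate_two_sided(k, n):
    """Oracle: sum of probabilities of all outcomes no more likely than k."""
    pk = math.comb(n, k)
    return sum(math.comb(n, j) for j in range(n + 1) if math.comb(n, j) <= pk) / 2 ** n


class TestBinomTwoSided:
    def test_balanced_counts_give_one(self):
        assert binom_two_sided(4, 8) == pytest.approx(1.0)

    def test_seven_of_eight(self):
        assert binom_two_sided(7, 8) == pytest.approx(18 / 256)

    def test_all_of_eight(self):
        assert binom_two_sided(8, 8) == pytest.approx(2 / 256)

    def test_matches_full_enumeration_up_to_n_12(self):
        for n in range(1, 13):
            for k in range(n + 1):
                assert binom_two_sided(k, n) == pytest.approx(
                    enumerate_two_sided(k, n), rel=1e-12), (k, n)

    def test_empty_sample_undefined(self):
        with pytest.raises(ValueError):
            binom_two_sided(0, 0)


class TestLagGroup:
    def test_same_stay_is_tied(self, make_dataset):
        ds = make_dataset([("p1", "F", 45, "2005-03-01", "2005-03-05", "I21", "E11")])
        assert lag_group(ds, "p1", "I21", "E11") == ("same_stay", "tied")

    @pytest.mark.parametrize("date_a,date_b,group,direction", [
        ("2004-01-01", "2004-02-15", "under_3_months", "A->B"),      # 45 days
        ("2006-01-01", "2004-01-01", "over_one_year", "B->A"),       # 731 days
        ("2004-01-01", "2004-03-31", "three_to_twelve_months", "A->B"),  # 90 days
        ("2004-01-01", "2004-12-26", "over_one_year", "A->B"),       # 360 days
    ])
    def test_boundaries_and_direction(self, make_dataset, date_a, date_b,
                                      group, direction):
        ds = make_dataset([
            ("p1", "F", 45, date_a, date_a, "I21", ""),
            ("p1", "F", 45, date_b, date_b, "E11", ""),
        ])
        assert lag_group(ds, "p1", "I21", "E11") == (group, direction)

    def test_same_date_different_stays_is_tied(self, make_dataset):
        ds = make_dataset([
            ("p1", "F", 45, "2005-03-01", "2005-03-02", "I21", ""),
            ("p1", "F", 45, "2005-03-01", "2005-03-03", "E11", ""),
        ])
        assert lag_group(ds, "p1", "I21", "E11") == ("under_3_months", "tied")

    def test_missing_diagnosis_rejected(self, two_stay_dataset):
        with pytest.raises(ValueError):
            lag_group(two_stay_dataset, "p2", "I21", "E11")


def days_apart_rows(pid, code_a, code_b, days):
    import pandas as pd
    d0 = pd.Timestamp("2004-01-01")
    d1 = d0 + pd.Timedelta(days=days)
    return [(pid, "F", 45, d0.date().isoformat(), d0.date().isoformat(), code_a, ""),
            (pid, "F", 45, d1.date().isoformat(), d1.date().isoformat(), code_b, "")]


class TestTORAnalysis:
    def test_counts_partition_both_diagnosed_patients(self, make_dataset):
        rows = []
        for i, days in enumerate([0, 10, 50, 120, 400, 800]):
            rows += days_apart_rows(f"p{i}", "I21", "E11", days)
        rows += days_apart_rows("q1", "E11", "I21", 30)  # reverse direction
        ds = make_dataset(rows)
        results = tor_analysis(ds, "I21", "E11")
        total = sum(r.n_ab + r.n_ba + r.n_tied for r in results)
        assert total == 7
        assert [r.group for r in results] == list(LAG_GROUPS)

    def test_seven_to_one_group(self, make_dataset):
        rows = []
        for i in range(7):
            rows += days_apart_rows(f"p{i}", "I21", "E11", 30)
        rows += days_apart_rows("q0", "E11", "I21", 30)
        ds = make_dataset(rows)
        res = {r.group: r for r in tor_analysis(ds, "I21", "E11")}
        g = res["under_3_months"]
        assert (g.n_ab, g.n_ba) == (7, 1)
        assert g.tor == pytest.approx(7.0)
        assert g.p_binom == pytest.approx(18 / 256)
        assert g.stars == ""

    def test_swapping_codes_inverts_tor_keeps_p(self, make_dataset):
        rows = []
        for i, days in enumerate([20, 40, 40, 200, 500]):
            rows += days_apart_rows(f"p{i}", "I21", "E11", days)
        rows += days_apart_rows("q0", "E11", "I21", 25)
        ds = make_dataset(rows)
        fwd = {r.group: r for r in tor_analysis(ds, "I21", "E11")}
        rev = {r.group: r for r in tor_analysis(ds, "E11", "I21")}
        for g in LAG_GROUPS:
            assert fwd[g].n_ab == rev[g].n_ba
            if fwd[g].p_binom is not None:
                assert fwd[g].p_binom == pytest.approx(rev[g].p_binom, rel=1e-12)
                if math.isfinite(fwd[g].tor) and fwd[g].tor > 0:
                    assert rev[g].tor == pytest.approx(1 / fwd[g].tor, rel=1e-12)

    def test_degenerate_direction_on_generator_output(self):
        cfg = SimConfig(
            n_patients=4_000,
            prevalence={"default": {"I10": 0.2, "A01": 0.10, "B02": 0.10}},
            planted_pairs=[PlantedPair(code_a="A01", code_b="B02",
                                       or_female=2.0, or_male=2.0,
                                       direction_prob=1.0, lag_days_mean=120.0)],
            seed=77)
        ds = washout_filter(generate(cfg))
        results = tor_analysis(ds, "A01", "B02")
        directed = [r for r in results if r.n_ab + r.n_ba > 0]
        assert directed
        for r in directed:
            assert r.n_ba == 0
            assert math.isinf(r.tor)
            assert r.p_binom == pytest.approx(binom_two_sided(r.n_ab, r.n_ab))

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(5e-5) == "***"
        assert significance_stars(0.2) == ""
        assert significance_stars(None) == ""
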