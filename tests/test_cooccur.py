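"""Contingency tables, Mantel–Haenszel pooling and the screening filters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from comorbiscan.cohort import StratifiedCohort, StratumKey
from comorbiscan.cooccur import (ContingencyTable2x2, NoEstimateError, ScreenConfig,
                                 UndefinedEstimateError, build_tables, crude_or,
                                 crude_rr, mh_pool, screen_pairs, screen_to_frame)
from comorbiscan.synthetic_claims import PlantedPair, SimConfig, generate
from comorbiscan.cohort import assign_strata, washout_filter


def make_cohort(strata: dict) -> StratifiedCohort:
    """Cohort from {StratumKey: [(patient_id, iterable_of_codes), ...]}."""
    pat_rows, diag_rows = [], []
    for key, members in strata.items():
        for pid, codes in members:
            pat_rows.append((pid, key.sex, key.age_band_10y, key.period_start))
            diag_rows.extend((pid, c) for c in codes)
    patients = pd.DataFrame(pat_rows, columns=["patient_id", "sex", "age_band_10y",
                                               "period_start"]).set_index("patient_id")
    diag = pd.DataFrame(diag_rows, columns=["patient_id", "code"])
    return StratifiedCohort(patients=patients, diagnoses_long=diag)


def stratum_members(a, b, c, d, code_a="I21", code_b="E11", prefix="p"):
    members = []
    k = 0
    for count, codes in ((a, {code_a, code_b}), (b, {code_a}), (c, {code_b}), (d, set())):
        for _ in range(count):
            members.append((f"{prefix}{k}", codes))
            k += 1
    return members


KEY_F = StratumKey("F", 40, 2003)
KEY_F2 = StratumKey("F", 40, 2005)


class TestBuildTables:
    def test_counts_cross_tabulation(self):
        cohort = make_cohort({KEY_F: stratum_members(10, 5, 2, 8)})
        (t,) = build_tables(cohort, "I21", "E11", min_cell=1)
        assert t.cells() == (10, 5, 2, 8)
        assert not t.excluded
        # under the registry default (>4) the 2-patient cell excludes it
        (t4,) = build_tables(cohort, "I21", "E11")
        assert t4.excluded

    def test_cell_of_exactly_four_is_excluded(self):
        cohort = make_cohort({KEY_F: stratum_members(4, 6, 6, 9)})
        (t,) = build_tables(cohort, "I21", "E11")
        assert t.a == 4 and t.excluded  # inclusion rule is strictly > 4

    def test_empty_stratum_produces_no_table(self):
        cohort = make_cohort({KEY_F: stratum_members(10, 5, 2, 8)})
        tables = build_tables(cohort, "I21", "E11")
        assert len(tables) == 1  # only the populated stratum appears

    def test_identical_codes_rejected(self):
        cohort = make_cohort({KEY_F: stratum_members(1, 1, 1, 1)})
        with pytest.raises(ValueError):
            build_tables(cohort, "I21", "I21")


class TestCrudeEstimates:
    def test_crude_or_by_hand(self):
        assert crude_or(ContingencyTable2x2(10, 5, 2, 8)) == pytest.approx(8.0)

    @pytest.mark.parametrize("k", [1, 3, 17])
    def test_symmetric_table_gives_unity(self, k):
        assert crude_or(ContingencyTable2x2(k, k, k, k)) == pytest.approx(1.0)

    def test_zero_denominator_signals_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            crude_or(ContingencyTable2x2(10, 0, 2, 8))

    def test_crude_rr_by_hand(self):
        # [10/15] / [2/10]
        assert crude_rr(ContingencyTable2x2(10, 5, 2, 8)) == pytest.approx(10 / 3)


class TestMHPool:
    def test_single_stratum_reduces_to_crude(self):
        est = mh_pool([ContingencyTable2x2(10, 5, 2, 8)])
        assert est.or_mh == pytest.approx(8.0, rel=1e-12)
        assert est.rr_mh == pytest.approx(10 / 3, rel=1e-12)

    def test_two_strata_hand_arithmetic(self):
        est = mh_pool([ContingencyTable2x2(10, 5, 2, 8),
                       ContingencyTable2x2(4, 4, 4, 4)])
        # OR: (3.2 + 1.0)/(0.4 + 1.0); RR: (4.0 + 2.0)/(1.2 + 2.0)
        assert est.or_mh == pytest.approx(3.0, rel=1e-12)
        assert est.rr_mh == pytest.approx(1.875, rel=1e-12)

    def test_cmh_statistic_single_table(self):
        # hypergeometric mean 15*12/25 = 7.2, variance 15*10*12*13/(25^2*24) = 1.56
        # chi2 = (10-7.2)^2/1.56 = 5.0256..., p = P(chi2_1 > 5.0256)
        est = mh_pool([ContingencyTable2x2(10, 5, 2, 8)])
        assert est.p_cmh == pytest.approx(0.0249747, abs=1e-6)

    def test_permutation_invariant(self):
        tables = [ContingencyTable2x2(10, 5, 2, 8), ContingencyTable2x2(6, 7, 9, 11),
                  ContingencyTable2x2(5, 5, 6, 7)]
        ref = mh_pool(tables)
        for perm in itertools.permutations(tables):
            est = mh_pool(list(perm))
            assert est.or_mh == pytest.approx(ref.or_mh, rel=1e-12)
            assert est.p_cmh == pytest.approx(ref.p_cmh, rel=1e-12)

    def test_homogeneous_strata_return_common_or(self):
        t = ContingencyTable2x2(12, 6, 5, 20)
        est = mh_pool([t, t, t])
        assert est.or_mh == pytest.approx(crude_or(t), rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.tuples(*[st.integers(5, 60)] * 4), min_size=1, max_size=5))
    def test_ci_geometric_mean_equals_point_estimate(self, cells):
        tables = [ContingencyTable2x2(*c) for c in cells]
        est = mh_pool(tables)
        lo, hi = est.ci95_or
        assert math.sqrt(lo * hi) == pytest.approx(est.or_mh, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a1=st.integers(5, 40), a2=st.integers(5, 40),
           r1=st.integers(50, 120), c1=st.integers(50, 120), n=st.integers(200, 400))
    def test_pooling_identical_margins_stays_within_crude_range(self, a1, a2, r1, c1, n):
        tables = []
        for a in (a1, a2):
            b, c = r1 - a, c1 - a
            d = n - a - b - c
            assume(min(b, c, d) > 4)
            tables.append(ContingencyTable2x2(a, b, c, d))
        crude = [crude_or(t) for t in tables]
        est = mh_pool(tables)
        assert min(crude) - 1e-9 <= est.or_mh <= max(crude) + 1e-9

    def test_empty_input_and_all_excluded(self):
        with pytest.raises(ValueError):
            mh_pool([])
        with pytest.raises(NoEstimateError):
            mh_pool([ContingencyTable2x2(4, 9, 9, 9, excluded=True)])


class TestScreenPairs:
    def _audit_cohort(self):
        # code X reaches only 999 female patients; Y and Z are common in both
        strata = {}
        f_members = []
        for i in range(999):
            f_members.append((f"f{i}", {"A01", "B02", "C03"}))
        for i in range(999, 2100):
            f_members.append((f"f{i}", {"B02", "C03"} if i % 2 else {"B02"}))
        m_members = [(f"m{i}", {"A01", "B02", "C03"}) for i in range(1100)]
        m_members += [(f"m{i}", {"B02"}) for i in range(1100, 2200)]
        strata[StratumKey("F", 40, 2003)] = f_members
        strata[StratumKey("M", 40, 2003)] = m_members
        return make_cohort(strata)

    def test_occurrence_filter_drops_every_pair_of_rare_code(self):
        results = screen_pairs(self._audit_cohort(), ["A01", "B02", "C03"],
                               ScreenConfig(min_occurrences=1000))
        by_pair = {(r.code_a, r.code_b): r for r in results}
        for pair, r in by_pair.items():
            if "A01" in pair:
                assert "occurrence" in r.flags and not r.kept
                assert r.estimate_f is None and r.estimate_m is None
            else:
                assert "occurrence" not in r.flags

    def test_screen_recovers_only_the_planted_pair(self):
        cfg = SimConfig(
            n_patients=100_000,
            prevalence={"default": {
                "I10": 0.12, "M54": 0.07, "K29": 0.05, "N39": 0.06, "J18": 0.04,
                "A01": 0.05, "B02": 0.05}},
            planted_pairs=[PlantedPair(code_a="A01", code_b="B02",
                                       or_female=4.0, or_male=4.0)],
            seed=2024)
        strat = assign_strata(washout_filter(generate(cfg)),
                              bands=tuple(range(20, 80, 10)))
        universe = sorted(cfg.prevalence["default"])
        results = screen_pairs(strat, universe, ScreenConfig())
        kept = [(r.code_a, r.code_b) for r in results if r.kept]
        assert kept == [("A01", "B02")]

    def test_edge_frame_has_one_row_per_pair_and_sex(self):
        results = screen_pairs(self._audit_cohort(), ["B02", "C03"],
                               ScreenConfig(min_occurrences=100, min_cell=0))
        frame = screen_to_frame(results)
        assert len(frame) == 2
        assert set(frame["sex"]) == {"F", "M"}
        assert {"or_mh", "rr_mh", "ci_low", "ci_high", "p_cmh", "kept", "flags"
                } <= set(frame.columns)
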