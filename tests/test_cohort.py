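from datetime import date

import pandas as pd
import pytest

from tpmrisk import cohort
from tpmrisk.errors import CohortError, DataError
from tpmrisk.vocab_tpm import _as_date

from conftest import diag, make_claims

CRIT = cohort.CohortCriteria()


class TestIdentifyCases:
    def test_two_outpatient_with_prior_pso(self):
        claims = make_claims(
            [
                diag("A", "2004-01-01", "696.1"),
                diag("A", "2005-01-01", "696.0"),
                diag("A", "2005-06-01", "696.0"),
            ]
        )
        (m,) = cohort.identify_cases(claims, CRIT)
        assert m.label == "case"
        assert m.index_date == date(2005, 1, 1)

    def test_single_outpatient_not_a_case(self):
        claims = make_claims(
            [diag("A", "2004-01-01", "696.1"), diag("A", "2005-01-01", "696.0")]
        )
        assert cohort.identify_cases(claims, CRIT) == []

    @pytest.mark.parametrize("n_out", [0, 1, 2])
    @pytest.mark.parametrize("n_in", [0, 1])
    def test_count_combinations(self, n_out, n_in):
        # enumerate outpatient x inpatient 696.0 counts against the rule
        rows = [diag("A", "2003-01-01", "696.1")]
        for i in range(n_out):
            rows.append(diag("A", f"2005-0{i + 1}-01", "696.0", "outpatient"))
        for i in range(n_in):
            rows.append(diag("A", f"2006-0{i + 1}-01", "696.0", "inpatient"))
        cases = cohort.identify_cases(make_claims(rows), CRIT)
        expected = n_out >= 2 or n_in >= 1
        assert bool(cases) is expected

    def test_pso_after_psa_excluded(self):
        claims = make_claims(
            [
                diag("A", "2005-01-01", "696.0"),
                diag("A", "2005-06-01", "696.0"),
                diag("A", "2006-01-01", "696.1"),
            ]
        )
        assert cohort.identify_cases(claims, CRIT) == []

    def test_no_pso_excluded(self):
        claims = make_claims(
            [diag("A", "2005-01-01", "696.0"), diag("A", "2005-06-01", "696.0")]
        )
        assert cohort.identify_cases(claims, CRIT) == []

    def test_index_is_earliest_psa_of_any_setting(self):
        claims = make_claims(
            [
                diag("A", "2003-01-01", "696.8"),
                diag("A", "2004-05-01", "696.0", "inpatient"),
                diag("A", "2004-06-01", "696.0"),
                diag("A", "2004-07-01", "696.0"),
            ]
        )
        (m,) = cohort.identify_cases(claims, CRIT)
        assert m.index_date == date(2004, 5, 1)

    def test_malformed_code_reports_row(self):
        claims = make_claims([diag("A", "2004-01-01", "696.1")])
        claims.loc[0, "code"] = ""
        with pytest.raises(DataError, match="row 0"):
            cohort.identify_cases(claims, CRIT)


class TestControlPool:
    def test_pso_only_patient_in_pool(self):
        claims = make_claims(
            [diag("A", "2004-01-01", "696.1"), diag("A", "2008-03-05", "714")]
        )
        (m,) = cohort.identify_control_pool(claims, CRIT)
        assert m.label == "control"
        assert m.index_date == date(2008, 3, 5)  # last record of any kind

    def test_case_patient_excluded(self):
        claims = make_claims(
            [
                diag("A", "2004-01-01", "696.1"),
                diag("A", "2005-01-01", "696.0"),
                diag("A", "2005-06-01", "696.0"),
            ]
        )
        assert cohort.identify_control_pool(claims, CRIT) == []

    def test_empty_claims(self):
        claims = make_claims([])
        assert cohort.identify_control_pool(claims, CRIT) == []

    def test_disjoint_from_cases(self, sim_bundle):
        _, claims, _, _ = sim_bundle
        case_ids = {m.patient_id for m in cohort.identify_cases(claims, CRIT)}
        pool_ids = {m.patient_id for m in cohort.identify_control_pool(claims, CRIT)}
        assert case_ids and pool_ids
        assert not case_ids & pool_ids


class TestEligibility:
    @staticmethod
    def _demo(pid="A", birth="1970-01-01", sex="F"):
        return pd.DataFrame(
            {"patient_id": [pid], "birth_date": pd.to_datetime([birth]), "sex": [sex]}
        )

    @staticmethod
    def _claim_span(pid, first, last):
        return make_claims([diag(pid, first, "696.1"), diag(pid, last, "696.1")])

    def test_age_boundary_removed(self):
        m = cohort.CohortMember("A", "control", date(2010, 1, 1))
        claims = self._claim_span("A", "2004-01-01", "2010-01-01")
        kept = cohort.apply_eligibility([m], claims, self._demo(birth="2005-06-01"), CRIT)
        assert kept == []  # aged 4 at index

    def test_age_5_kept(self):
        m = cohort.CohortMember("A", "control", date(2010, 1, 1))
        claims = self._claim_span("A", "2004-01-01", "2010-01-01")
        kept = cohort.apply_eligibility([m], claims, self._demo(birth="2004-12-01"), CRIT)
        assert len(kept) == 1 and kept[0].age_at_index == 5

    def test_155_week_span_removed(self):
        m = cohort.CohortMember("A", "control", date(2009, 12, 21))
        first = date(2009, 12, 21) - pd.Timedelta(days=155 * 7)
        claims = self._claim_span("A", first.isoformat(), "2009-12-21")
        assert cohort.apply_eligibility([m], claims, self._demo(), CRIT) == []

    def test_missing_demographics_raises(self):
        m = cohort.CohortMember("ZZ", "control", date(2010, 1, 1))
        with pytest.raises(DataError, match="ZZ"):
            cohort.apply_eligibility([m], self._claim_span("ZZ", "2004-01-01", "2010-01-01"),
                                     self._demo(pid="A"), CRIT)

    def test_window_must_fit_before_index(self):
        # 156-week span but index at the very start: window cannot precede it
        m = cohort.CohortMember("A", "case", date(2005, 1, 1))
        claims = self._claim_span("A", "2005-01-01", "2008-01-01")
        assert cohort.apply_eligibility([m], claims, self._demo(), CRIT) == []

    def test_hand_built_subset(self):
        # ten members with known ages/spans; survivors derived by hand
        rows, demo_rows, members, expected = [], [], [], set()
        scenarios = [
            ("P0", 40, "2003-01-01", "2010-01-01", date(2009, 6, 1), True),
            ("P1", 4, "2003-01-01", "2010-01-01", date(2009, 6, 1), False),   # too young
            ("P2", 100, "2003-01-01", "2010-01-01", date(2009, 6, 1), False),  # too old
            ("P3", 40, "2008-01-01", "2010-01-01", date(2009, 6, 1), False),  # short span
            ("P4", 40, "2003-01-01", "2010-01-01", date(2004, 6, 1), False),  # window early
            ("P5", 40, "2003-01-01", "2010-01-01", date(2014, 6, 1), False),  # index outside
            ("P6", 5, "2003-01-01", "2010-01-01", date(2009, 6, 1), True),    # boundary age
            ("P7", 99, "2003-01-01", "2010-01-01", date(2009, 6, 1), True),   # boundary age
            ("P8", 40, "2004-01-01", "2006-12-20", date(2006, 6, 1), False),  # short span
            ("P9", 40, "2002-01-01", "2013-12-01", date(2013, 6, 1), True),
        ]
        for pid, age, first, last, index, keep in scenarios:
            rows += [diag(pid, first, "696.1"), diag(pid, last, "696.1")]
            birth = index - pd.Timedelta(days=int(age * 365.25) + 30)
            demo_rows.append((pid, birth, "M"))
            members.append(cohort.CohortMember(pid, "control", index))
            if keep:
                expected.add(pid)
        demo = pd.DataFrame(demo_rows, columns=["patient_id", "birth_date", "sex"])
        demo["birth_date"] = pd.to_datetime(demo["birth_date"])
        kept = cohort.apply_eligibility(members, make_claims(rows), demo, CRIT)
        assert {m.patient_id for m in kept} == expected


class TestSampleControls:
    @staticmethod
    def _pool(n):
        return [
            cohort.CohortMember(f"C{i:05d}", "control", date(2010, 1, 1)) for i in range(n)
        ]

    def test_study_ratio_443_to_1772(self):
        sampled = cohort.sample_controls(self._pool(2000), 443, CRIT)
        assert len(sampled) == 1772

    def test_zero_cases(self):
        assert cohort.sample_controls(self._pool(10), 0, CRIT) == []

    def test_deterministic(self):
        a = cohort.sample_controls(self._pool(100), 10, CRIT)
        b = cohort.sample_controls(self._pool(100), 10, CRIT)
        assert [m.patient_id for m in a] == [m.patient_id for m in b]

    def test_seed_changes_sample(self):
        a = cohort.sample_controls(self._pool(500), 20, CRIT)
        crit2 = cohort.CohortCriteria(sampling_seed=99)
        b = cohort.sample_controls(self._pool(500), 20, crit2)
        assert [m.patient_id for m in a] != [m.patient_id for m in b]

    def test_pool_too_small(self):
        with pytest.raises(CohortError, match="deficit 12"):
            cohort.sample_controls(self._pool(28), 10, CRIT)


class TestOnSimulatedData:
    def test_exact_ground_truth_recovery(self, sim_bundle, sim_cohort):
        _, _, _, truth = sim_bundle
        _, cases, _, _ = sim_cohort
        truth_cases = truth[truth["true_label"] == "case"]
        assert {m.patient_id for m in cases} == set(truth_cases["patient_id"])
        idx = dict(zip(truth_cases["patient_id"], truth_cases["true_index_date"]))
        assert all(_as_date(idx[m.patient_id]) == m.index_date for m in cases)

    def test_ratio_and_disjointness(self, sim_cohort):
        _, cases, _, controls = sim_cohort
        assert len(controls) == 4 * len(cases)
        assert not {m.patient_id for m in cases} & {m.patient_id for m in controls}

    def test_all_members_pass_eligibility(self, sim_bundle, sim_cohort):
        _, claims, demo, _ = sim_bundle
        crit, cases, _, controls = sim_cohort
        again = cohort.apply_eligibility(cases + controls, claims, demo, crit)
        assert len(again) == len(cases) + len(controls)
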