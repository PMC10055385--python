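from datetime import date

import pandas as pd
import pytest

from tpmrisk import cohort as cohort_mod
from tpmrisk import synth
from tpmrisk import vocab_tpm as vt


def make_claims(rows):
    """Build a claims frame from (pid, iso_date, kind, code, setting, days)."""
    df = pd.DataFrame(
        rows, columns=["patient_id", "event_date", "kind", "code", "setting", "days_supplied"]
    )
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def diag(pid, day, code, setting="outpatient"):
    return (pid, day, "diagnosis", code, setting, None)


def rx(pid, day, code, days):
    return (pid, day, "prescription", code, None, days)


@pytest.fixture(scope="session")
def sim_bundle():
    """Small planted-signal population shared across cross-module tests."""
    cfg = synth.SimConfig(n_cases=60, control_ratio=4, seed=11, risk_codes={"714": 5.0})
    claims, demo, truth = synth.simulate_population(cfg)
    return cfg, claims, demo, truth


@pytest.fixture(scope="session")
def sim_cohort(sim_bundle):
    _, claims, demo, _ = sim_bundle
    crit = cohort_mod.CohortCriteria()
    cases = cohort_mod.apply_eligibility(
        cohort_mod.identify_cases(claims, crit), claims, demo, crit
    )
    pool = cohort_mod.apply_eligibility(
        cohort_mod.identify_control_pool(claims, crit), claims, demo, crit
    )
    controls = cohort_mod.sample_controls(pool, len(cases), crit)
    return crit, cases, pool, controls


@pytest.fixture(scope="session")
def sim_maps(sim_bundle, sim_cohort):
    _, claims, _, _ = sim_bundle
    _, cases, _, controls = sim_cohort
    vocab = vt.compact_vocabulary(claims)
    maps, _ = vt.build_cohort_tpms(cases + controls, claims, vocab, vt.WindowSpec())
    return vocab, maps


@pytest.fixture()
def simple_member():
    return cohort_mod.CohortMember(
        patient_id="PX", label="case", index_date=date(2010, 6, 15), age_at_index=40, sex="F"
    )
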