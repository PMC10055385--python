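"""Case/control cohort construction from a claims stream.

Cases are patients with a qualifying arthropathy code pattern (>=2
outpatient 696.0 claims or >=1 inpatient claim) preceded strictly by a
psoriasis code (696.1/696.8); their index date is the first 696.0 claim.
Controls are psoriasis patients without the qualifying pattern; their index
date is the last available record.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import CohortError, DataError
from .vocab_tpm import WindowSpec, age_at, _as_date

__all__ = [
    "CohortCriteria",
    "CohortMember",
    "identify_cases",
    "identify_control_pool",
    "apply_eligibility",
    "sample_controls",
    "build_cohort",
    "members_to_frame",
    "frame_to_members",
]


@dataclass(frozen=True)
class CohortCriteria:
    psa_code: str = "696.0"
    pso_codes: tuple[str, ...] = ("696.1", "696.8")
    min_outpatient_psa: int = 2
    min_inpatient_psa: int = 1
    age_range: tuple[int, int] = (5, 99)
    min_record_span_weeks: int = 156
    enrollment_interval: tuple[date, date] = (date(2002, 1, 1), date(2013, 12, 31))
    control_ratio: int = 4
    sampling_seed: int = 0
    windows: WindowSpec = WindowSpec()

    def __post_init__(self) -> None:
        if self.age_range[0] > self.age_range[1]:
            raise DataError("age_range must be ordered")
        if self.min_record_span_weeks <= self.windows.total_weeks - 1:
            raise DataError("min_record_span must cover observation + prediction windows")


@dataclass(frozen=True)
class CohortMember:
    patient_id: str
    label: str  # "case" | "control"
    index_date: date
    age_at_index: int | None = None
    sex: str | None = None


def _check_codes(claims: pd.DataFrame) -> None:
    codes = claims["code"]
    bad = codes.isna() | (codes.astype(str).str.strip() == "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(f"malformed code string at claims row {row}")


def _qualifying_psa(sub: pd.DataFrame, criteria: CohortCriteria):
    """(qualifies, first_psa_date or None) for one patient's claims."""
    psa = sub[(sub["kind"] == "diagnosis") & (sub["code"] == criteria.psa_code)]
    if psa.empty:
        return False, None
    n_out = int((psa["setting"] == "outpatient").sum())
    n_in = int((psa["setting"] == "inpatient").sum())
    ok = n_out >= criteria.min_outpatient_psa or n_in >= criteria.min_inpatient_psa
    return ok, _as_date(psa["event_date"].min())


def identify_cases(claims: pd.DataFrame, criteria: CohortCriteria) -> list[CohortMember]:
    """Patients meeting the arthropathy pattern with a strictly earlier
    psoriasis code; index date = first 696.0 claim date."""
    _check_codes(claims)
    out: list[CohortMember] = []
    for pid, sub in claims.groupby("patient_id", sort=True):
        ok, first_psa = _qualifying_psa(sub, criteria)
        if not ok:
            continue
        pso = sub[(sub["kind"] == "diagnosis") & sub["code"].isin(criteria.pso_codes)]
        if pso.empty or _as_date(pso["event_date"].min()) >= first_psa:
            continue
        out.append(CohortMember(patient_id=str(pid), label="case", index_date=first_psa))
    return out


def identify_control_pool(claims: pd.DataFrame, criteria: CohortCriteria) -> list[CohortMember]:
    """Psoriasis patients without a qualifying arthropathy pattern; index
    date = last record of any kind."""
    _check_codes(claims)
    out: list[CohortMember] = []
    for pid, sub in claims.groupby("patient_id", sort=True):
        ok, _ = _qualifying_psa(sub, criteria)
        if ok:
            continue
        pso = sub[(sub["kind"] == "diagnosis") & sub["code"].isin(criteria.pso_codes)]
        if pso.empty:
            continue
        out.append(
            CohortMember(
                patient_id=str(pid), label="control", index_date=_as_date(sub["event_date"].max())
            )
        )
    return out


def apply_eligibility(
    members: list[CohortMember],
    claims: pd.DataFrame,
    demographics: pd.DataFrame,
    criteria: CohortCriteria,
) -> list[CohortMember]:
    """Keep members aged within range at index, with >= min_record_span
    weeks of records inside the enrollment interval, an index date inside
    that interval, and a fully observed observation + prediction window
    before the index date.  Fills in age and sex."""
    demo = demographics.set_index("patient_id")
    lo, hi = criteria.enrollment_interval
    span_days = criteria.min_record_span_weeks * 7
    window_days = criteria.windows.total_weeks * 7
    grouped = dict(tuple(claims.groupby("patient_id", sort=False)))
    kept: list[CohortMember] = []
    for m in members:
        if m.patient_id not in demo.index:
            raise DataError(f"missing demographics row for patient {m.patient_id}")
        row = demo.loc[m.patient_id]
        age = age_at(_as_date(row["birth_date"]), m.index_date)
        if not criteria.age_range[0] <= age <= criteria.age_range[1]:
            continue
        if not lo <= m.index_date <= hi:
            continue
        sub = grouped.get(m.patient_id)
        if sub is None:
            continue
        dates = sub["event_date"]
        dates = dates[(dates >= pd.Timestamp(lo)) & (dates <= pd.Timestamp(hi))]
        if dates.empty:
            continue
        first, last = _as_date(dates.min()), _as_date(dates.max())
        if (last - first).days < span_days:
            continue
        if first > m.index_date - timedelta(days=window_days):
            continue  # observation + prediction windows not fully observed
        kept.append(replace(m, age_at_index=age, sex=str(row["sex"])))
    return kept


def sample_controls(
    pool: list[CohortMember], n_cases: int, criteria: CohortCriteria
) -> list[CohortMember]:
    """Uniform, seeded sampling of control_ratio * n_cases controls."""
    need = criteria.control_ratio * n_cases
    if len(pool) < need:
        raise CohortError(
            f"control pool too small: need {need}, have {len(pool)} (deficit {need - len(pool)})"
        )
    if need == 0:
        return []
    ordered = sorted(pool, key=lambda m: m.patient_id)
    rng = np.random.default_rng(criteria.sampling_seed)
    idx = rng.choice(len(ordered), size=need, replace=False)
    return [ordered[i] for i in sorted(idx)]


def build_cohort(
    claims: pd.DataFrame, demographics: pd.DataFrame, criteria: CohortCriteria
) -> list[CohortMember]:
    """Full pipeline: identify, filter for eligibility, sample controls."""
    cases = apply_eligibility(identify_cases(claims, criteria), claims, demographics, criteria)
    pool = apply_eligibility(
        identify_control_pool(claims, criteria), claims, demographics, criteria
    )
    controls = sample_controls(pool, len(cases), criteria)
    return cases + controls


def members_to_frame(members: list[CohortMember]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in members],
            "label": [m.label for m in members],
            "index_date": [m.index_date.isoformat() for m in members],
            "age_at_index": [m.age_at_index for m in members],
            "sex": [m.sex for m in members],
        }
    )


def frame_to_members(df: pd.DataFrame) -> list[CohortMember]:
    return [
        CohortMember(
            patient_id=str(r.patient_id),
            label=str(r.label),
            index_date=_as_date(r.index_date),
            age_at_index=int(r.age_at_index) if pd.notna(r.age_at_index) else None,
            sex=str(r.sex) if pd.notna(r.sex) else None,
        )
        for r in df.itertuples(index=False)
    ]
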