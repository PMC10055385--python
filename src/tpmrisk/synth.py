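"""Seeded synthetic claims populations with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-patient weekly Poisson visit processes, per-visit diagnosis and
prescription draws, a case subpopulation with a qualifying arthropathy code
pattern at a planted index date, and elevated "risk code" rates confined to
the observation window so temporal models have signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .vocab_tpm import WindowSpec, truncate_diagnosis

__all__ = [
    "PSA_CODE",
    "PSO_CODES",
    "SimConfig",
    "simulate_population",
    "write_claims",
    "read_claims",
]

PSA_CODE = "696.0"
PSO_CODES = ("696.1", "696.8")

_DEFAULT_BG = {
    "250": 0.05, "272": 0.05, "300": 0.04, "401": 0.08, "414": 0.03,
    "585": 0.02, "691": 0.03, "710": 0.01, "714": 0.02, "720": 0.01,
    "733": 0.02, "780": 0.06,
}
_DEFAULT_DRUGS = {
    "N02BA01": 0.06, "M01AB05": 0.05, "L04AX03": 0.01, "D05AX02": 0.01,
    "H02AB06": 0.02, "A07EC01": 0.01,
}
_DEFAULT_DAYS = {7: 0.4, 14: 0.3, 28: 0.2, 30: 0.1}


@dataclass
class SimConfig:
    """Parameters of one synthetic population draw."""

    n_cases: int = 100
    control_ratio: int = 4
    n_controls: int | None = None  # overrides control_ratio * n_cases when set
    seed: int = 0
    calendar_span: tuple[date, date] = (date(1999, 1, 1), date(2013, 12, 31))
    enrollment_start: date = date(2002, 1, 1)
    visit_rate: float = 0.5
    background_code_freqs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BG))
    risk_codes: dict[str, float] = field(default_factory=dict)
    risk_ramp: bool = False
    drug_code_freqs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DRUGS))
    drug_days_dist: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_DAYS))
    age_dist: tuple[float, float] = (45.0, 18.0)
    sex_ratio: float = 0.55
    inpatient_fraction: float = 0.1
    pso_revisit_prob: float = 0.02
    extra_span_weeks_max: int = 40
    windows: WindowSpec = field(default_factory=WindowSpec)

    def validate(self) -> None:
        if not isinstance(self.n_cases, (int, np.integer)) or self.n_cases < 0:
            raise ConfigurationError("n_cases must be a non-negative integer")
        if not isinstance(self.control_ratio, (int, np.integer)) or self.control_ratio <= 0:
            raise ConfigurationError("control_ratio must be a positive integer")
        if self.n_controls is not None and self.n_controls < 0:
            raise ConfigurationError("n_controls must be non-negative")
        if self.visit_rate <= 0:
            raise ConfigurationError("visit_rate must be positive")
        for name in ("sex_ratio", "inpatient_fraction", "pso_revisit_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for code, p in self.background_code_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"background_code_freqs[{code!r}] must lie in [0, 1]")
            if truncate_diagnosis(code) == "696":
                raise ConfigurationError(
                    f"background_code_freqs may not contain the 696 family ({code!r})"
                )
        for code, m in self.risk_codes.items():
            if code not in self.background_code_freqs:
                raise ConfigurationError(f"risk_codes[{code!r}] is not a background code")
            if m < 0:
                raise ConfigurationError(f"risk_codes[{code!r}] multiplier must be >= 0")
        for code, p in self.drug_code_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"drug_code_freqs[{code!r}] must lie in [0, 1]")
        total = sum(self.drug_days_dist.values())
        if not self.drug_days_dist or abs(total - 1.0) > 1e-9:
            raise ConfigurationError("drug_days_dist probabilities must sum to 1")
        for d in self.drug_days_dist:
            if not 1 <= int(d) <= 90:
                raise ConfigurationError("drug_days_dist support must lie in 1..90")
        start, end = self.calendar_span
        min_weeks = 161 + self.extra_span_weeks_max
        if (end - max(start, self.enrollment_start)).days < min_weeks * 7:
            raise ConfigurationError("calendar_span too short for the required record spans")


def simulate_population(config: SimConfig):
    """Generate (claims, demographics, truth) tables for one population.

    ``claims`` columns: patient_id, event_date, kind, code, setting,
    days_supplied.  Deterministic for a fixed config + seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_controls = (
        config.n_controls if config.n_controls is not None else config.control_ratio * config.n_cases
    )

    bg_codes = list(config.background_code_freqs)
    bg_probs = np.array([config.background_code_freqs[c] for c in bg_codes])
    drug_codes = list(config.drug_code_freqs)
    drug_probs = np.array([config.drug_code_freqs[c] for c in drug_codes])
    day_choices = np.array(sorted(config.drug_days_dist), dtype=int)
    day_probs = np.array([config.drug_days_dist[d] for d in sorted(config.drug_days_dist)])
    day_probs = day_probs / day_probs.sum()

    claims_rows: list[tuple] = []
    demo_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    total = config.n_cases + n_controls
    for i in range(total):
        is_case = i < config.n_cases
        pid = f"P{i + 1:06d}"
        _simulate_patient(
            pid, is_case, config, rng, bg_codes, bg_probs, drug_codes, drug_probs,
            day_choices, day_probs, claims_rows, demo_rows, truth_rows,
        )

    claims = pd.DataFrame(
        claims_rows,
        columns=["patient_id", "event_date", "kind", "code", "setting", "days_supplied"],
    )
    claims = claims.sort_values(
        ["patient_id", "event_date", "kind", "code"], kind="stable"
    ).reset_index(drop=True)
    claims["event_date"] = pd.to_datetime(claims["event_date"])
    demographics = pd.DataFrame(demo_rows, columns=["patient_id", "birth_date", "sex"])
    demographics["birth_date"] = pd.to_datetime(demographics["birth_date"])
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "true_label", "true_index_date", "planted_risk_codes"]
    )
    truth["true_index_date"] = pd.to_datetime(truth["true_index_date"])
    return claims, demographics, truth


def _simulate_patient(
    pid, is_case, cfg, rng, bg_codes, bg_probs, drug_codes, drug_probs,
    day_choices, day_probs, claims_rows, demo_rows, truth_rows,
):
    windows = cfg.windows
    total_weeks = windows.total_weeks  # 156 by default
    span_weeks = total_weeks + 5 + int(rng.integers(0, cfg.extra_span_weeks_max + 1))
    cal_start, cal_end = cfg.calendar_span
    earliest = max(cal_start, cfg.enrollment_start)
    slack = (cal_end - earliest).days - span_weeks * 7
    first_day = earliest + timedelta(days=int(rng.integers(0, slack + 1)))
    last_day = first_day + timedelta(days=span_weeks * 7)

    if is_case:
        # jitter >= 1 keeps the first record strictly before the observation
        # window, so index placement alone cannot separate cases from controls
        jitter = 1 + int(rng.integers(0, 14))
        index_date = first_day + timedelta(days=total_weeks * 7 + jitter)
    else:
        index_date = last_day

    obs_start = index_date - timedelta(days=total_weeks * 7)
    obs_end = index_date - timedelta(days=windows.prediction_weeks * 7)  # exclusive

    # demographics: age at index drawn from age_dist, clipped so eligibility holds
    mean, sd = cfg.age_dist
    age = float(np.clip(rng.normal(mean, sd), 8.0, 92.0))
    birth_date = index_date - timedelta(days=int(age * 365.25) + int(rng.integers(0, 365)))
    sex = "M" if rng.random() < cfg.sex_ratio else "F"
    demo_rows.append((pid, birth_date.isoformat(), sex))

    # weekly Poisson visit process, plus forced visits on the span endpoints
    counts = rng.poisson(cfg.visit_rate, size=span_weeks)
    visit_days = [first_day, last_day]
    for w in range(span_weeks):
        for _ in range(int(counts[w])):
            visit_days.append(first_day + timedelta(days=w * 7 + int(rng.integers(0, 7))))
    visit_days.sort()

    obs_span_days = max((obs_end - obs_start).days, 1)
    for day in visit_days:
        in_obs = obs_start <= day < obs_end
        # diagnoses
        probs = bg_probs
        if is_case and cfg.risk_codes and in_obs:
            probs = bg_probs.copy()
            for j, code in enumerate(bg_codes):
                mult = cfg.risk_codes.get(code)
                if mult is None:
                    continue
                if cfg.risk_ramp:
                    frac = (day - obs_start).days / obs_span_days
                    mult = 1.0 + (mult - 1.0) * frac
                probs[j] = min(probs[j] * mult, 1.0)
        hits = rng.random(len(bg_codes)) < probs
        for j in np.flatnonzero(hits):
            setting = "inpatient" if rng.random() < cfg.inpatient_fraction else "outpatient"
            claims_rows.append((pid, day.isoformat(), "diagnosis", bg_codes[j], setting, None))
        # recurring psoriasis code, same rate in both groups
        if rng.random() < cfg.pso_revisit_prob:
            claims_rows.append((pid, day.isoformat(), "diagnosis", PSO_CODES[0], "outpatient", None))
        # prescriptions attached to a subset of visits
        dhits = rng.random(len(drug_codes)) < drug_probs
        for j in np.flatnonzero(dhits):
            days_supplied = int(rng.choice(day_choices, p=day_probs))
            claims_rows.append(
                (pid, day.isoformat(), "prescription", drug_codes[j], None, days_supplied)
            )

    # psoriasis diagnoses anchor the record span: one at the very first
    # record (strictly before any index) and one at the last span day, so
    # record spans and control index dates are exact by construction
    claims_rows.append((pid, first_day.isoformat(), "diagnosis", PSO_CODES[0], "outpatient", None))
    claims_rows.append((pid, last_day.isoformat(), "diagnosis", PSO_CODES[0], "outpatient", None))

    if is_case:
        # qualifying arthropathy pattern anchored at the planted index date
        if rng.random() < cfg.inpatient_fraction:
            claims_rows.append((pid, index_date.isoformat(), "diagnosis", PSA_CODE, "inpatient", None))
        else:
            claims_rows.append((pid, index_date.isoformat(), "diagnosis", PSA_CODE, "outpatient", None))
            second = index_date + timedelta(days=int(rng.integers(7, 22)))
            claims_rows.append((pid, second.isoformat(), "diagnosis", PSA_CODE, "outpatient", None))

    truth_rows.append(
        (
            pid,
            "case" if is_case else "control",
            index_date.isoformat(),
            ";".join(sorted(cfg.risk_codes)) if is_case else "",
        )
    )


def write_claims(claims: pd.DataFrame, demographics: pd.DataFrame, out_dir, truth=None) -> None:
    """Write the population as plain CSVs (claims.csv, demographics.csv,
    and truth.csv when ground truth is supplied)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = claims.copy()
    c["event_date"] = pd.to_datetime(c["event_date"]).dt.strftime("%Y-%m-%d")
    c["days_supplied"] = c["days_supplied"].astype("Int64")
    c.to_csv(out / "claims.csv", index=False)
    d = demographics.copy()
    d["birth_date"] = pd.to_datetime(d["birth_date"]).dt.strftime("%Y-%m-%d")
    d.to_csv(out / "demographics.csv", index=False)
    if truth is not None:
        t = truth.copy()
        t["true_index_date"] = pd.to_datetime(t["true_index_date"]).dt.strftime("%Y-%m-%d")
        t.to_csv(out / "truth.csv", index=False)


def read_claims(in_dir):
    """Round-trip reader for :func:`write_claims` output."""
    p = Path(in_dir)
    claims = pd.read_csv(
        p / "claims.csv",
        parse_dates=["event_date"],
        dtype={"patient_id": str, "kind": str, "code": str, "setting": str},
    )
    claims["days_supplied"] = claims["days_supplied"].astype("Int64")
    demographics = pd.read_csv(
        p / "demographics.csv", parse_dates=["birth_date"], dtype={"patient_id": str, "sex": str}
    )
    truth_path = p / "truth.csv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(
            truth_path, parse_dates=["true_index_date"], dtype={"patient_id": str}
        )
        truth["planted_risk_codes"] = truth["planted_risk_codes"].fillna("")
    return claims, demographics, truth
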