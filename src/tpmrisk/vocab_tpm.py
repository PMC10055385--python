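"""Code vocabularies and temporal phenomic map (TPM) encoding.

A TPM is a ``codes x weeks`` matrix for one patient: diagnosis rows hold
weekly claim counts, drug rows hold weekly days-supplied, and all cells are
scaled into [0, 1] by per-row training-set maxima.  Row 0 is the first
diagnosis code, column 0 the oldest week of the observation window.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, MappingError

__all__ = [
    "WindowSpec",
    "Vocabulary",
    "TemporalPhenomicMap",
    "NormalizationStats",
    "truncate_diagnosis",
    "truncate_drug",
    "default_diagnosis_codes",
    "default_drug_codes",
    "build_vocabulary",
    "compact_vocabulary",
    "week_of",
    "window_bounds",
    "build_tpm",
    "build_cohort_tpms",
    "fit_normalization",
    "normalize_maps",
    "stack_maps",
    "save_tpm_store",
    "load_tpm_store",
    "age_at",
]

_DIAG_RE = re.compile(r"^(V?)(\d{1,3})(?:\.\d{1,2})?$")


@dataclass(frozen=True)
class WindowSpec:
    """Observation / prediction window lengths, in whole weeks."""

    observation_weeks: int = 131
    prediction_weeks: int = 25

    def __post_init__(self) -> None:
        if self.observation_weeks <= 0 or self.prediction_weeks <= 0:
            raise DataError("window lengths must be positive")

    @property
    def total_weeks(self) -> int:
        return self.observation_weeks + self.prediction_weeks


@dataclass(frozen=True)
class Vocabulary:
    """Ordered diagnosis + drug code blocks with a code -> row bijection."""

    diagnosis_codes: tuple[str, ...]
    drug_codes: tuple[str, ...]
    row_index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        idx = {c: i for i, c in enumerate(self.diagnosis_codes)}
        off = len(self.diagnosis_codes)
        for j, c in enumerate(self.drug_codes):
            if c in idx:
                raise DataError(f"duplicate vocabulary code {c!r}")
            idx[c] = off + j
        object.__setattr__(self, "row_index", idx)

    @property
    def n_rows(self) -> int:
        return len(self.diagnosis_codes) + len(self.drug_codes)

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for c in self.diagnosis_codes + self.drug_codes:
            h.update(c.encode())
            h.update(b"\0")
        return h.hexdigest()[:16]


@dataclass
class TemporalPhenomicMap:
    patient_id: str
    matrix: np.ndarray  # (n_rows, observation_weeks) float32
    age: float
    sex: str  # "M" | "F"
    label: int  # 1 = case, 0 = control


@dataclass
class NormalizationStats:
    """Per-row maxima fitted on training maps only."""

    row_max: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        denom = np.where(self.row_max > 0, self.row_max, 1.0)
        out = matrix / denom[:, None]
        return np.clip(out, 0.0, 1.0).astype(np.float32)

    def to_json(self) -> str:
        return json.dumps({"row_max": self.row_max.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "NormalizationStats":
        return cls(row_max=np.asarray(json.loads(s)["row_max"], dtype=np.float64))


def truncate_diagnosis(code: str) -> str:
    """Reduce an ICD-9-CM code to its 3-character category.

    Numeric codes map to zero-padded ``"001"``..``"999"``; V-codes map to
    ``"V01"``..``"V99"``.  E-codes and anything else raise MappingError.
    """
    if not isinstance(code, str):
        raise MappingError(f"diagnosis code must be a string, got {code!r}")
    m = _DIAG_RE.match(code.strip())
    if not m:
        raise MappingError(f"unmappable diagnosis code {code!r}")
    prefix, digits = m.groups()
    if prefix == "V":
        if len(digits) > 2 and "." not in code:
            # V-codes carry a 2-digit category; a 3-digit integer part is junk
            raise MappingError(f"unmappable diagnosis code {code!r}")
        num = int(digits[:2]) if len(digits) > 2 else int(digits)
        if not 1 <= num <= 99:
            raise MappingError(f"V-code out of range: {code!r}")
        return f"V{num:02d}"
    num = int(digits)
    if not 1 <= num <= 999:
        raise MappingError(f"diagnosis code out of range: {code!r}")
    return f"{num:03d}"


def truncate_drug(code: str) -> str:
    """Reduce an ATC code to its category: first 5 characters, or the full
    7 characters when the 5th character is 'X' (case-insensitive)."""
    if not isinstance(code, str) or len(code.strip()) < 5:
        raise MappingError(f"ATC code too short: {code!r}")
    code = code.strip().upper()
    if code[4] == "X":
        if len(code) < 7:
            raise MappingError(f"ATC code with 'X' fifth character needs 7 characters: {code!r}")
        return code[:7]
    return code[:5]


def default_diagnosis_codes() -> tuple[str, ...]:
    """The 1098-entry diagnosis block: 001..999 then V01..V99."""
    numeric = tuple(f"{i:03d}" for i in range(1, 1000))
    vcodes = tuple(f"V{i:02d}" for i in range(1, 100))
    return numeric + vcodes


def default_drug_codes() -> tuple[str, ...]:
    """The packaged synthetic ATC formulary (830 categories)."""
    text = resources.files("tpmrisk.data").joinpath("atc_formulary.txt").read_text()
    return tuple(text.split())


def build_vocabulary(drug_codes: tuple[str, ...] | None = None) -> Vocabulary:
    return Vocabulary(
        diagnosis_codes=default_diagnosis_codes(),
        drug_codes=tuple(drug_codes) if drug_codes is not None else default_drug_codes(),
    )


def compact_vocabulary(claims: pd.DataFrame) -> Vocabulary:
    """A reduced vocabulary holding only the code categories observed in a
    claims table.  Useful for small simulation experiments where the full
    1928-row map would be mostly empty."""
    diag: set[str] = set()
    drug: set[str] = set()
    for kind, code in zip(claims["kind"], claims["code"]):
        try:
            if kind == "diagnosis":
                diag.add(truncate_diagnosis(code))
            else:
                drug.add(truncate_drug(code))
        except MappingError:
            continue
    return Vocabulary(diagnosis_codes=tuple(sorted(diag)), drug_codes=tuple(sorted(drug)))


def week_of(index_date: date, event_date: date, windows: WindowSpec) -> int | None:
    """Observation-window column for an event, or None if out of window.

    Week ``w`` covers days ``[index - (T - w) * 7, index - (T - w - 1) * 7)``
    with ``T = observation + prediction`` weeks, so the last observation
    column ends ``prediction_weeks`` whole weeks before the index date.
    """
    delta = (index_date - event_date).days
    if delta <= 0:
        return None
    w = windows.total_weeks - math.ceil(delta / 7)
    if 0 <= w < windows.observation_weeks:
        return w
    return None


def window_bounds(index_date: date, windows: WindowSpec) -> tuple[date, date]:
    """(first day covered, first day AFTER the observation window)."""
    start = index_date - timedelta(days=windows.total_weeks * 7)
    end_exclusive = index_date - timedelta(days=windows.prediction_weeks * 7)
    return start, end_exclusive


def build_tpm(
    member,
    claims: pd.DataFrame,
    vocab: Vocabulary,
    windows: WindowSpec,
    norm: NormalizationStats | None = None,
    skip_counter: Counter | None = None,
) -> TemporalPhenomicMap:
    """Encode one cohort member's in-window claims as a TPM.

    ``claims`` may be the full claims table or already restricted to the
    patient.  Unmappable codes are skipped (tallied in ``skip_counter``).
    When ``norm`` is None the raw count/day matrix is returned.
    """
    mat = np.zeros((vocab.n_rows, windows.observation_weeks), dtype=np.float32)
    sub = claims[claims["patient_id"] == member.patient_id]
    index_date = _as_date(member.index_date)
    n_drug_days = windows.total_weeks * 7
    for row in sub.itertuples(index=False):
        event_date = _as_date(row.event_date)
        try:
            if row.kind == "diagnosis":
                code = truncate_diagnosis(row.code)
            else:
                code = truncate_drug(row.code)
        except MappingError:
            if skip_counter is not None:
                skip_counter[str(row.code)] += 1
            continue
        r = vocab.row_index.get(code)
        if r is None:
            if skip_counter is not None:
                skip_counter[code] += 1
            continue
        if row.kind == "diagnosis":
            w = week_of(index_date, event_date, windows)
            if w is not None:
                mat[r, w] += 1.0
        else:
            days = int(row.days_supplied)
            delta0 = (index_date - event_date).days
            if delta0 > n_drug_days + days or delta0 <= 0 and delta0 - days + 1 <= 0:
                continue  # all supplied days fall outside the window
            deltas = delta0 - np.arange(days)
            valid = deltas > 0
            weeks = windows.total_weeks - np.ceil(deltas[valid] / 7).astype(int)
            weeks = weeks[(weeks >= 0) & (weeks < windows.observation_weeks)]
            np.add.at(mat[r], weeks, 1.0)
    if norm is not None:
        mat = norm.transform(mat)
    return TemporalPhenomicMap(
        patient_id=member.patient_id,
        matrix=mat,
        age=float(member.age_at_index),
        sex=member.sex,
        label=1 if getattr(member, "label", "control") == "case" else 0,
    )


def build_cohort_tpms(
    members,
    claims: pd.DataFrame,
    vocab: Vocabulary,
    windows: WindowSpec,
    norm: NormalizationStats | None = None,
) -> tuple[list[TemporalPhenomicMap], Counter]:
    """Encode every member; returns (maps, skipped-code tally)."""
    skip: Counter = Counter()
    grouped = dict(tuple(claims.groupby("patient_id", sort=False)))
    maps = []
    for m in members:
        sub = grouped.get(m.patient_id)
        if sub is None:
            sub = claims.iloc[0:0]
        maps.append(build_tpm(m, sub, vocab, windows, norm=norm, skip_counter=skip))
    return maps, skip


def fit_normalization(maps: list[TemporalPhenomicMap]) -> NormalizationStats:
    """Per-row maxima over the TRAINING maps only."""
    if not maps:
        raise DataError("fit_normalization needs at least one training map")
    row_max = np.zeros(maps[0].matrix.shape[0], dtype=np.float64)
    for m in maps:
        np.maximum(row_max, m.matrix.max(axis=1), out=row_max)
    return NormalizationStats(row_max=row_max)


def normalize_maps(
    maps: list[TemporalPhenomicMap], stats: NormalizationStats
) -> list[TemporalPhenomicMap]:
    return [
        TemporalPhenomicMap(
            patient_id=m.patient_id,
            matrix=stats.transform(m.matrix),
            age=m.age,
            sex=m.sex,
            label=m.label,
        )
        for m in maps
    ]


def stack_maps(maps: list[TemporalPhenomicMap]):
    """Stack maps into model-ready arrays.

    Returns ``(X, aux, y, ids)`` where X is (n, rows, weeks) float32, aux is
    (n, 2) with age/100 and sex (M=1, F=0), y is (n,) int labels.
    """
    X = np.stack([m.matrix for m in maps]).astype(np.float32)
    aux = np.array(
        [[m.age / 100.0, 1.0 if m.sex == "M" else 0.0] for m in maps], dtype=np.float32
    )
    y = np.array([m.label for m in maps], dtype=np.int64)
    ids = [m.patient_id for m in maps]
    return X, aux, y, ids


def save_tpm_store(
    maps: list[TemporalPhenomicMap],
    vocab: Vocabulary,
    windows: WindowSpec,
    out_dir,
    norm: NormalizationStats | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, aux, y, ids = stack_maps(maps)
    np.savez_compressed(out / "tpm.npz", X=X, aux=aux, y=y, ids=np.asarray(ids))
    sidecar = {
        "vocabulary_hash": vocab.content_hash(),
        "n_diagnosis_codes": len(vocab.diagnosis_codes),
        "n_drug_codes": len(vocab.drug_codes),
        "observation_weeks": windows.observation_weeks,
        "prediction_weeks": windows.prediction_weeks,
        "row0": "first diagnosis code",
        "col0": "oldest week",
        "normalization": json.loads(norm.to_json()) if norm is not None else None,
    }
    (out / "tpm.json").write_text(json.dumps(sidecar, indent=2))


def load_tpm_store(in_dir):
    data = np.load(Path(in_dir) / "tpm.npz", allow_pickle=False)
    meta = json.loads((Path(in_dir) / "tpm.json").read_text())
    return data["X"], data["aux"], data["y"], list(data["ids"]), meta


def age_at(birth_date: date, ref_date: date) -> int:
    """Completed years between birth and reference date."""
    b, r = _as_date(birth_date), _as_date(ref_date)
    years = r.year - b.year
    if (r.month, r.day) < (b.month, b.day):
        years -= 1
    return years


def _as_date(d) -> date:
    if isinstance(d, date) and not hasattr(d, "hour"):
        return d
    return pd.Timestamp(d).date()
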