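"""Occlusion-sensitivity feature importance and logistic odds ratios.

Importance of a feature (one vocabulary code, or a clinical group of codes,
or the age/sex auxiliary inputs) is the relative AUROC change when the
feature's rows are zeroed in every test map and the SAME trained model is
re-scored: ``loss_percent = (auroc_occluded - auroc_full) / auroc_full *
100`` (negative = degradation).  Each feature is occluded independently
against the intact baseline (leave-one-out); cumulative elimination is
available behind a flag but makes losses order-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import model as model_mod
from . import vocab_tpm as vt
from .errors import FeatureError
from .evaluate import roc_auc

__all__ = [
    "FeatureGroup",
    "ImportanceEntry",
    "occlude",
    "auroc_loss",
    "rank_features",
    "single_code_features",
    "load_feature_groups",
    "default_feature_groups",
    "logistic_ors",
]


@dataclass(frozen=True)
class FeatureGroup:
    """A set of map rows and/or auxiliary inputs occluded together.  An
    empty group is allowed and occludes nothing (loss exactly 0)."""

    name: str
    rows: tuple[int, ...] = ()
    include_age: bool = False
    include_sex: bool = False


@dataclass
class ImportanceEntry:
    feature: FeatureGroup
    auroc_full: float
    auroc_occluded: float
    loss_percent: float
    odds_ratio: float | None = None
    or_ci: tuple[float, float] | None = None
    p_value: float | None = None


def occlude(maps, feature: FeatureGroup, aux_fill: tuple[float, float] | None = None):
    """Copies of the maps with the feature's rows zeroed across all weeks.

    When the feature occludes age or sex, those auxiliary values are
    replaced by ``aux_fill`` (training-set means, as (age/100, sex01));
    defaults to the mean over the supplied maps.  Inputs are never mutated.
    """
    n_rows = maps[0].matrix.shape[0]
    for r in feature.rows:
        if not 0 <= r < n_rows:
            raise FeatureError(f"feature {feature.name!r}: row {r} outside 0..{n_rows - 1}")
    if aux_fill is None and (feature.include_age or feature.include_sex):
        mean_age = float(np.mean([m.age for m in maps]))
        mean_sex = float(np.mean([1.0 if m.sex == "M" else 0.0 for m in maps]))
        aux_fill = (mean_age / 100.0, mean_sex)
    out = []
    rows = list(feature.rows)
    for m in maps:
        mat = m.matrix.copy()
        if rows:
            mat[rows, :] = 0.0
        age, sex = m.age, m.sex
        if feature.include_age:
            age = aux_fill[0] * 100.0
        if feature.include_sex:
            sex = "M" if aux_fill[1] >= 0.5 else "F"
        out.append(
            vt.TemporalPhenomicMap(
                patient_id=m.patient_id, matrix=mat, age=age, sex=sex, label=m.label
            )
        )
    return out


def auroc_loss(
    net: "model_mod.Network",
    maps,
    labels=None,
    feature: FeatureGroup | None = None,
    baseline: float | None = None,
    aux_fill: tuple[float, float] | None = None,
) -> ImportanceEntry:
    """Relative AUROC change when one feature is occluded (no refit)."""
    y = np.asarray(labels) if labels is not None else np.array([m.label for m in maps])
    if baseline is None:
        baseline = roc_auc(model_mod.predict(net, maps), y, ci=None).value
    occ = occlude(maps, feature, aux_fill=aux_fill)
    auc_occ = roc_auc(model_mod.predict(net, occ), y, ci=None).value
    loss = (auc_occ - baseline) / baseline * 100.0
    return ImportanceEntry(
        feature=feature, auroc_full=baseline, auroc_occluded=auc_occ, loss_percent=loss
    )


def rank_features(
    net: "model_mod.Network",
    maps,
    labels=None,
    features: list[FeatureGroup] = (),
    cumulative: bool = False,
) -> list[ImportanceEntry]:
    """One occlusion per feature against the intact baseline, sorted by
    loss_percent ascending (most damaging first); ties break by name."""
    if not features:
        raise FeatureError("features must be nonempty")
    y = np.asarray(labels) if labels is not None else np.array([m.label for m in maps])
    baseline = roc_auc(model_mod.predict(net, maps), y, ci=None).value
    mean_age = float(np.mean([m.age for m in maps])) / 100.0
    mean_sex = float(np.mean([1.0 if m.sex == "M" else 0.0 for m in maps]))
    aux_fill = (mean_age, mean_sex)
    entries = []
    current = maps
    for feat in features:
        target = current if cumulative else maps
        e = auroc_loss(net, target, y, feat, baseline=baseline, aux_fill=aux_fill)
        entries.append(e)
        if cumulative:
            current = occlude(current, feat, aux_fill=aux_fill)
    return sorted(entries, key=lambda e: (e.loss_percent, e.feature.name))


def single_code_features(vocab: vt.Vocabulary, codes=None) -> list[FeatureGroup]:
    """One FeatureGroup per vocabulary code (or per listed code)."""
    if codes is None:
        codes = list(vocab.diagnosis_codes) + list(vocab.drug_codes)
    return [FeatureGroup(name=c, rows=(vocab.row_index[c],)) for c in codes]


def load_feature_groups(cfg: dict, vocab: vt.Vocabulary) -> list[FeatureGroup]:
    """Build groups from a ``{name: [codes] | "age" | "sex"}`` mapping,
    silently dropping codes absent from the vocabulary."""
    groups = []
    for name, codes in cfg.items():
        if codes == "age":
            groups.append(FeatureGroup(name=name, include_age=True))
            continue
        if codes == "sex":
            groups.append(FeatureGroup(name=name, include_sex=True))
            continue
        rows = tuple(vocab.row_index[c] for c in codes if c in vocab.row_index)
        if rows:
            groups.append(FeatureGroup(name=name, rows=rows))
    return groups


def default_feature_groups(vocab: vt.Vocabulary) -> list[FeatureGroup]:
    text = resources.files("tpmrisk.data").joinpath("feature_groups.yaml").read_text()
    return load_feature_groups(yaml.safe_load(text), vocab)


def logistic_ors(
    members,
    claims: pd.DataFrame,
    predictors: list[str],
    windows: vt.WindowSpec | None = None,
    multivariable: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Logistic-regression odds ratios for code predictors of case status.

    Predictors are coded as presence/absence of the code category during
    each member's observation window.  Returns a frame with or, ci_low,
    ci_high, p_value, significant and non_estimable columns.  Perfectly
    separating predictors are flagged non-estimable; the run continues.
    """
    import statsmodels.api as sm

    windows = windows or vt.WindowSpec()
    y = np.array([1 if m.label == "case" else 0 for m in members])
    if len(np.unique(y)) < 2:
        raise FeatureError("both outcome classes must be present")
    X = _presence_matrix(members, claims, predictors, windows)
    sep = []
    for j in range(X.shape[1]):
        x = X[:, j]
        # a predictor identical (or complementary) to the outcome separates
        if np.array_equal(x, y) or np.array_equal(x, 1 - y):
            sep.append(j)
    usable = [j for j in range(X.shape[1]) if j not in sep]
    rows = []
    if multivariable:
        fits = {tuple(usable): usable} if usable else {}
    else:
        fits = {(j,): [j] for j in usable}
    results: dict[int, tuple] = {}
    for _, cols in fits.items():
        exog = sm.add_constant(X[:, cols].astype(float), has_constant="add")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
            params = res.params[1:]
            ci = res.conf_int(alpha)[1:]
            pvals = res.pvalues[1:]
            bse = res.bse[1:]
            for k, j in enumerate(cols):
                if not np.isfinite(bse[k]) or bse[k] > 50:
                    results[j] = None
                else:
                    results[j] = (
                        float(np.exp(params[k])),
                        float(np.exp(ci[k][0])),
                        float(np.exp(ci[k][1])),
                        float(pvals[k]),
                    )
        except Exception:
            for j in cols:
                results[j] = None
    for j, code in enumerate(predictors):
        r = results.get(j)
        if j in sep or r is None:
            rows.append(
                {
                    "predictor": code, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "significant": False, "non_estimable": True,
                }
            )
        else:
            orv, lo, hi, p = r
            rows.append(
                {
                    "predictor": code, "or": orv, "ci_low": lo, "ci_high": hi,
                    "p_value": p, "significant": bool(p < 0.05), "non_estimable": False,
                }
            )
    return pd.DataFrame(rows)


def _presence_matrix(members, claims, predictors, windows) -> np.ndarray:
    grouped = dict(tuple(claims.groupby("patient_id", sort=False)))
    X = np.zeros((len(members), len(predictors)), dtype=int)
    pred_set = {c: j for j, c in enumerate(predictors)}
    for i, m in enumerate(members):
        sub = grouped.get(m.patient_id)
        if sub is None:
            continue
        index_date = vt._as_date(m.index_date)
        for row in sub.itertuples(index=False):
            try:
                if row.kind == "diagnosis":
                    code = vt.truncate_diagnosis(row.code)
                else:
                    code = vt.truncate_drug(row.code)
            except Exception:
                continue
            j = pred_set.get(code)
            if j is None or X[i, j]:
                continue
            if vt.week_of(index_date, vt._as_date(row.event_date), windows) is not None:
                X[i, j] = 1
    return X
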