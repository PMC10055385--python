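"""Holdout split, 5-fold cross-validation and ROC-based evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from . import model as model_mod
from . import vocab_tpm as vt
from .errors import MetricError, SplitError

__all__ = [
    "SplitPlan",
    "AUROC",
    "EvalResult",
    "split",
    "roc_auc",
    "optimal_threshold",
    "confusion_metrics",
    "crossvalidate",
]


@dataclass(frozen=True)
class SplitPlan:
    holdout_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0
    stratified: bool = True


@dataclass
class AUROC:
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str | None = None


@dataclass
class EvalResult:
    fold_metrics: list[dict]
    mean: dict
    sd: dict
    holdout_auroc: AUROC
    holdout_threshold: float
    holdout_metrics: dict
    details: dict = field(default_factory=dict)


def split(labels, plan: SplitPlan):
    """Partition sample indices into a holdout set and CV folds.

    Returns ``(folds, train_idx, holdout_idx)`` where ``folds`` is a list of
    (fit_idx, val_idx) pairs; all indices refer to the original array.  The
    holdout never appears in any fold.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < plan.n_folds + 1:
        raise SplitError(f"{n} samples cannot support {plan.n_folds} folds plus a holdout")
    idx = np.arange(n)
    strat = y if plan.stratified else None
    train_idx, holdout_idx = train_test_split(
        idx, test_size=plan.holdout_fraction, random_state=plan.seed, stratify=strat
    )
    if plan.stratified:
        kf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
        fold_iter = kf.split(train_idx, y[train_idx])
    else:
        kf = KFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
        fold_iter = kf.split(train_idx)
    folds = [(train_idx[fi], train_idx[vi]) for fi, vi in fold_iter]
    return folds, np.sort(train_idx), np.sort(holdout_idx)


def roc_auc(
    scores,
    labels,
    ci: str | None = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AUROC:
    """AUROC as the normalized Mann-Whitney U statistic (ties count 1/2).

    ``ci`` is "bootstrap" (stratified percentile), "normal"
    (Hanley-McNeil), or None.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    value = _auc(s, y)
    if ci is None:
        return AUROC(value=value)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y != 1)
    if ci == "normal":
        n1, n0 = len(pos), len(neg)
        a = value
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
        )
        from scipy.stats import norm

        zc = norm.ppf(1 - alpha / 2)
        return AUROC(value, max(0.0, a - zc * se), min(1.0, a + zc * se), "normal")
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            bi = np.concatenate([bp, bn])
            reps[i] = _auc(s[bi], y[bi])
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return AUROC(value, float(lo), float(hi), "bootstrap")
    raise ValueError(f"unknown ci method {ci!r}")


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise MetricError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def optimal_threshold(scores, labels) -> float:
    """Observed score maximizing sensitivity + specificity (scores >=
    threshold are classed positive); ties resolved toward the lowest such
    threshold, i.e. the most sensitive operating point."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise MetricError("threshold undefined: both classes must be present")
    cand = np.unique(s)
    pos_sorted = np.sort(s[y == 1])
    neg_sorted = np.sort(s[y != 1])
    tp = n1 - np.searchsorted(pos_sorted, cand, side="left")
    fp = n0 - np.searchsorted(neg_sorted, cand, side="left")
    j = tp / n1 + (n0 - fp) / n0
    best = np.flatnonzero(j == j.max())[0]
    return float(cand[best])


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Sensitivity/specificity/PPV/NPV at a threshold; ratios with a zero
    denominator are reported as NaN, not zero."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y != 1)))
    fp = int(np.sum(pred & (y != 1)))

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def crossvalidate(
    raw_maps: list,
    plan: SplitPlan,
    spec: "model_mod.ModelSpec",
    ci: str = "bootstrap",
) -> EvalResult:
    """Cross-validated training and holdout evaluation on RAW (unnormalized)
    maps.  Normalization is fitted inside each fold on that fold's training
    maps only, and on the full training set for the final model, so holdout
    and validation samples never leak into the normalization statistics."""
    y = np.array([m.label for m in raw_maps])
    folds, train_idx, holdout_idx = split(y, plan)
    fold_metrics: list[dict] = []
    details: dict = {"fold_norm_row_max": []}
    for f, (fit_idx, val_idx) in enumerate(folds):
        fit_maps = [raw_maps[i] for i in fit_idx]
        val_maps = [raw_maps[i] for i in val_idx]
        norm = vt.fit_normalization(fit_maps)
        details["fold_norm_row_max"].append(norm.row_max.copy())
        fit_n = vt.normalize_maps(fit_maps, norm)
        val_n = vt.normalize_maps(val_maps, norm)
        fold_spec = replace(spec, seed=spec.seed * 1000 + f)
        net = model_mod.build_model(fold_spec, fit_n[0].matrix.shape)
        model_mod.train(net, fit_n, spec=fold_spec)
        scores = model_mod.predict(net, val_n)
        auc = roc_auc(scores, y[val_idx], ci=None).value
        thr = optimal_threshold(scores, y[val_idx])
        cm = confusion_metrics(scores, y[val_idx], thr)
        fold_metrics.append({"fold": f, "auroc": auc, "threshold": thr, **cm})
    keys = ("auroc", "sensitivity", "specificity", "ppv", "npv", "threshold")
    mean = {k: float(np.nanmean([fm[k] for fm in fold_metrics])) for k in keys}
    sd = {k: float(np.nanstd([fm[k] for fm in fold_metrics], ddof=1)) for k in keys}
    # final model: full training set, scored once on the untouched holdout
    train_maps = [raw_maps[i] for i in train_idx]
    norm = vt.fit_normalization(train_maps)
    details["final_norm_row_max"] = norm.row_max.copy()
    train_n = vt.normalize_maps(train_maps, norm)
    net = model_mod.build_model(spec, train_n[0].matrix.shape)
    model_mod.train(net, train_n, spec=spec)
    holdout_n = vt.normalize_maps([raw_maps[i] for i in holdout_idx], norm)
    h_scores = model_mod.predict(net, holdout_n)
    h_auc = roc_auc(h_scores, y[holdout_idx], ci=ci, seed=plan.seed)
    h_thr = optimal_threshold(h_scores, y[holdout_idx])
    h_cm = confusion_metrics(h_scores, y[holdout_idx], h_thr)
    details["holdout_scores"] = h_scores
    details["holdout_idx"] = holdout_idx
    details["final_model"] = net
    details["final_norm"] = norm
    return EvalResult(
        fold_metrics=fold_metrics,
        mean=mean,
        sd=sd,
        holdout_auroc=h_auc,
        holdout_threshold=h_thr,
        holdout_metrics=h_cm,
        details=details,
    )
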