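"""Diagnostic evaluation: ROC/AUC, plateau time constant, Youden cutoff.

The question the analysis answers is how well the day-to-day coefficient of
variation of resistance separates asthmatic from non-asthmatic subjects:

* ``auc_mann_whitney`` — rank-based AUC, equal to the probability that a
  random asthmatic scores above a random non-asthmatic (ties counted 1/2),
  with a seeded bootstrap CI.
* ``fit_auc_exponential`` — saturating-exponential fit of AUC versus time
  scale, AUC(t) = A_plateau - (A_plateau - A0)·exp(-t/tau); 5·tau (rounded
  up to whole days) is the minimum observation period to reach the plateau.
* ``crossval_youden_cutoff`` — stratified k-fold cross-validation of the
  Youden-optimal threshold (max sensitivity + specificity - 1 on the
  training folds); reports both fold-averaged held-out performance and the
  pooled confusion matrix at the mean cutoff, with Wilson CIs for the
  proportions and a log-normal CI for the diagnostic odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint


class DiagnosticsError(ValueError):
    """Invalid inputs to a diagnostic computation."""


# ---------------------------------------------------------------------------
# AUC


@dataclass
class RocResult:
    """Rank AUC with bootstrap CI and the full ROC curve.

    Orientation: higher score = more asthma-like; positives are asthmatic.
    """

    auc: float
    auc_ci: tuple[float, float]
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) with ties counted 1/2, via mid-ranks."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    return (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _threshold_grid(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus -inf and +inf."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _confusion_at(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for the rule: predict positive iff score >= cutoff."""
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def auc_mann_whitney(
    positives: np.ndarray,
    negatives: np.ndarray,
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = 0,
) -> RocResult:
    """Rank-based AUC of positives vs negatives with a bootstrap CI.

    Set ``n_boot=0`` to skip the bootstrap (CI reported as (nan, nan)).
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise DiagnosticsError("both groups must be non-empty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise DiagnosticsError("non-finite score encountered")
    auc = _rank_auc(pos, neg)

    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    thr = _threshold_grid(scores)
    sens = np.array([np.mean(pos >= c) for c in thr])
    spec = np.array([np.mean(neg < c) for c in thr])

    if n_boot > 0:
        rng = np.random.default_rng(rng)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(len(pos), size=len(pos))]
            bn = neg[rng.integers(len(neg), size=len(neg))]
            boots[b] = _rank_auc(bp, bn)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    return RocResult(
        auc=float(auc),
        auc_ci=ci,
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        n_pos=len(pos),
        n_neg=len(neg),
    )


# ---------------------------------------------------------------------------
# exponential plateau fit


@dataclass
class ExpFit:
    """Saturating exponential AUC(t) = A_plateau - (A_plateau - A0)·exp(-t/tau)."""

    A0: float
    A_plateau: float
    tau: float
    r_squared: float
    min_observation_days: int  # ceil(5 * tau)


def fit_auc_exponential(scales: np.ndarray, aucs: np.ndarray) -> ExpFit:
    """Least-squares exponential fit of AUC against time scale.

    Initialisation: plateau at the max AUC, A0 at the first AUC, tau at a
    third of the scale span; tau is bounded to (0, 10x span].
    """
    scales = np.asarray(scales, dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    if len(scales) < 4:
        raise DiagnosticsError("need at least 4 (scale, AUC) points")
    if np.any(np.diff(scales) <= 0):
        raise DiagnosticsError("scales must be strictly increasing")

    span = scales[-1] - scales[0]

    def model(t, a0, ap, tau):
        return ap - (ap - a0) * np.exp(-t / tau)

    p0 = (aucs[0], float(np.max(aucs)), span / 3)
    try:
        popt, _ = optimize.curve_fit(
            model,
            scales,
            aucs,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 10 * span]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise DiagnosticsError(f"exponential fit did not converge: {exc}") from exc
    a0, ap, tau = (float(v) for v in popt)
    resid = aucs - model(scales, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((aucs - aucs.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ExpFit(
        A0=a0,
        A_plateau=ap,
        tau=tau,
        r_squared=r2,
        min_observation_days=math.ceil(5 * tau - 1e-12),
    )


# ---------------------------------------------------------------------------
# cross-validated Youden cutoff


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest threshold maximizing Youden's J = sens + spec - 1.

    Candidates are midpoints between adjacent distinct scores plus ±inf; the
    smallest maximizer is returned (the tie-break that favours sensitivity).
    """
    thr = _threshold_grid(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    best_thr, best_j = thr[0], -np.inf
    for c in thr:
        tp, fp, fn, tn = _confusion_at(scores, labels, c)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_thr, best_j = c, j
    return float(best_thr)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Sensitivity, specificity and DOR with CIs from a confusion matrix.

    Wilson intervals for the proportions; log-normal interval for the DOR
    (Haldane 0.5 correction when a cell is empty).
    """
    if min(tp, fp, fn, tn) < 0:
        raise DiagnosticsError("confusion counts must be non-negative")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    sens_ci = proportion_confint(tp, tp + fn, alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=0.05, method="wilson")
    a, b, c, d = tp, fp, fn, tn
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    dor = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    dor_ci = (dor * math.exp(-1.96 * se_log), dor * math.exp(1.96 * se_log))
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "TN": tn,
        "sensitivity": float(sens),
        "sensitivity_ci": (float(sens_ci[0]), float(sens_ci[1])),
        "specificity": float(spec),
        "specificity_ci": (float(spec_ci[0]), float(spec_ci[1])),
        "dor": float(dor),
        "dor_ci": (float(dor_ci[0]), float(dor_ci[1])),
    }


@dataclass
class CutoffResult:
    """Cross-validated Youden cutoff and its diagnostic performance."""

    cutoff: float  # mean of fold cutoffs
    cutoff_ci: tuple[float, float]  # t-interval across folds
    fold_cutoffs: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    fold_dor: list[float]
    mean_sensitivity: float
    mean_specificity: float
    mean_dor: float
    pooled: dict = field(default_factory=dict)  # metrics at the mean cutoff


def crossval_youden_cutoff(
    values: np.ndarray,
    labels: np.ndarray,
    k_folds: int = 5,
    rng: int | None = 0,
) -> CutoffResult:
    """Stratified k-fold cross-validation of the Youden-optimal cutoff.

    Per fold the cutoff is chosen on the training portion and evaluated on
    the held-out portion (predict positive iff value >= cutoff).  Besides the
    fold-averaged held-out performance, the pooled confusion matrix obtained
    by applying the mean cutoff to all subjects is reported — the two need
    not agree exactly.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(values)):
        raise DiagnosticsError("non-finite score encountered")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if k_folds > min(n_pos, n_neg):
        raise DiagnosticsError(
            f"k_folds={k_folds} exceeds smallest class size {min(n_pos, n_neg)}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rng)
    fold_cut, fold_sens, fold_spec, fold_dor = [], [], [], []
    for train, test in skf.split(values.reshape(-1, 1), labels):
        c = youden_cutoff(values[train], labels[train])
        if not np.isfinite(c):  # degenerate training fold; fall back to median
            c = float(np.median(values[train]))
        tp, fp, fn, tn = _confusion_at(values[test], labels[test], c)
        m = confusion_metrics(tp, fp, fn, tn)
        fold_cut.append(c)
        fold_sens.append(m["sensitivity"])
        fold_spec.append(m["specificity"])
        fold_dor.append(m["dor"])

    cut = float(np.mean(fold_cut))
    if len(fold_cut) > 1 and np.std(fold_cut, ddof=1) > 0:
        half = stats.t.ppf(0.975, len(fold_cut) - 1) * stats.sem(fold_cut)
    else:
        half = 0.0
    pooled = confusion_metrics(*_confusion_at(values, labels, cut))
    return CutoffResult(
        cutoff=cut,
        cutoff_ci=(cut - half, cut + half),
        fold_cutoffs=[float(c) for c in fold_cut],
        fold_sensitivity=fold_sens,
        fold_specificity=fold_spec,
        fold_dor=fold_dor,
        mean_sensitivity=float(np.mean(fold_sens)),
        mean_specificity=float(np.mean(fold_spec)),
        mean_dor=float(np.mean(fold_dor)),
        pooled=pooled,
    )


# ---------------------------------------------------------------------------
# report orchestration


def diagnostic_report(
    table: pd.DataFrame,
    scheme: str = "mid_insp",
    scale: int = 14,
    k_folds: int = 5,
    seed: int = 0,
    n_boot: int = 2000,
) -> dict:
    """Full diagnostic evaluation from a variability long table.

    Computes the AUC at every available time scale for the scheme, fits the
    exponential plateau curve when at least 4 scales are present, and runs
    the cross-validated cutoff analysis at the requested scale.  Returns a
    JSON-serializable dict.
    """
    sub = table[table["scheme"] == scheme]
    if sub.empty:
        raise DiagnosticsError(f"no rows for scheme '{scheme}'")
    auc_by_scale = {}
    for s, tab in sub.groupby("scale"):
        pos = tab.loc[tab["group"] == "asthma", "CVR"].to_numpy()
        neg = tab.loc[tab["group"] != "asthma", "CVR"].to_numpy()
        if len(pos) == 0 or len(neg) == 0:
            continue
        auc_by_scale[int(s)] = _rank_auc(pos, neg)

    expfit = None
    if len(auc_by_scale) >= 4:
        sc = np.array(sorted(auc_by_scale))
        expfit = fit_auc_exponential(sc, np.array([auc_by_scale[s] for s in sc]))

    at_scale = sub[sub["scale"] == scale]
    if at_scale.empty:
        raise DiagnosticsError(f"no rows at scale {scale} for scheme '{scheme}'")
    pos = at_scale.loc[at_scale["group"] == "asthma", "CVR"].to_numpy()
    neg = at_scale.loc[at_scale["group"] != "asthma", "CVR"].to_numpy()
    roc = auc_mann_whitney(pos, neg, n_boot=n_boot, rng=seed)
    values = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    cut = crossval_youden_cutoff(values, labels, k_folds=k_folds, rng=seed)

    report = {
        "scheme": scheme,
        "scale": scale,
        "k_folds": k_folds,
        "seed": seed,
        "n_asthma": int(len(pos)),
        "n_other": int(len(neg)),
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci),
        "auc_by_scale": {str(k): float(v) for k, v in sorted(auc_by_scale.items())},
        "cutoff": cut.cutoff,
        "cutoff_ci": list(cut.cutoff_ci),
        "fold_cutoffs": cut.fold_cutoffs,
        "fold_averaged": {
            "sensitivity": cut.mean_sensitivity,
            "specificity": cut.mean_specificity,
            "dor": cut.mean_dor,
        },
        "pooled": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cut.pooled.items()
        },
        "ci_methods": {
            "sensitivity": "wilson",
            "specificity": "wilson",
            "dor": "log-normal (Haldane 0.5 on empty cells)",
            "auc": f"bootstrap percentile ({n_boot} resamples)",
            "cutoff": "t-interval across folds",
        },
    }
    if expfit is not None:
        report["exp_fit"] = {
            "A0": expfit.A0,
            "A_plateau": expfit.A_plateau,
            "tau": expfit.tau,
            "r_squared": expfit.r_squared,
            "min_observation_days": expfit.min_observation_days,
        }
    return report


def roc_table(roc: RocResult) -> pd.DataFrame:
    """Threshold grid of an ROC as a DataFrame (for roc.csv export)."""
    return pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )
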