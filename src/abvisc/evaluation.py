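"""Regression/classification metrics with bootstrap confidence intervals.

Viscosity predictions are evaluated by Spearman rank correlation, R^2 (on
log10 scale by default, matching the training target), and ROC-AUC for the
viscous (>= 20 cP) vs non-viscous classification, with the confusion matrix
taken at the ROC optimal operating point and 95% CIs from 500 paired
bootstrap resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DataError, DegenerateError

VISCOUS_CUTOFF_CP = 20.0


@dataclass
class MetricsReport:
    spearman: float
    r2: float
    roc_auc: float
    oop_cutoff: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    accuracy: float
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_bootstrap: int = 0
    oop_rule: str = "corner"


def regression_metrics(
    pred_cP, obs_cP, scale: str = "log10"
) -> tuple[float, float]:
    """(Spearman rho, R^2); R^2 on the configured scale (default log10)."""
    pred = np.asarray(pred_cP, float)
    obs = np.asarray(obs_cP, float)
    if pred.shape != obs.shape or len(pred) < 3:
        raise DataError("need >= 3 matched prediction/observation pairs")
    if np.ptp(obs) == 0:
        raise DegenerateError("constant observations: metrics undefined")
    rho = float(stats.spearmanr(pred, obs).statistic)
    if scale == "log10":
        pred, obs = np.log10(pred), np.log10(obs)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return rho, 1.0 - ss_res / ss_tot


def roc_analysis(
    pred_cP,
    obs_cP,
    class_cutoff: float = VISCOUS_CUTOFF_CP,
    oop_rule: str = "corner",
) -> tuple[float, float, np.ndarray]:
    """(AUC, optimal-operating-point cutoff in cP, confusion matrix at OOP).

    OOP: prediction threshold closest to the (FPR=0, TPR=1) corner (ties ->
    higher TPR); ``oop_rule='youden'`` maximizes TPR - FPR instead.
    """
    pred = np.asarray(pred_cP, float)
    obs = np.asarray(obs_cP, float)
    y = (obs >= class_cutoff).astype(int)
    if y.min() == y.max():
        raise DegenerateError("single-class observations: ROC undefined")
    auc = float(roc_auc_score(y, pred))
    fpr, tpr, thr = roc_curve(y, pred)
    if oop_rule == "corner":
        crit = fpr**2 + (1.0 - tpr) ** 2
    elif oop_rule == "youden":
        crit = -(tpr - fpr)
    else:
        raise DataError(f"unknown OOP rule {oop_rule!r}")
    # ties broken toward higher TPR
    best = min(range(len(thr)), key=lambda i: (crit[i], -tpr[i]))
    cutoff = float(thr[best])
    if not np.isfinite(cutoff):
        cutoff = float(pred.max())
    hat = (pred >= cutoff).astype(int)
    confusion = np.array(
        [
            [int(np.sum((y == 0) & (hat == 0))), int(np.sum((y == 0) & (hat == 1)))],
            [int(np.sum((y == 1) & (hat == 0))), int(np.sum((y == 1) & (hat == 1)))],
        ]
    )
    return auc, cutoff, confusion


def bootstrap_ci(
    metric_fn,
    pred_cP,
    obs_cP,
    n: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI over ``n`` paired resamples; undefined resamples are
    skipped (error if they exceed half)."""
    if n < 100:
        raise DataError("need >= 100 bootstrap resamples")
    pred = np.asarray(pred_cP, float)
    obs = np.asarray(obs_cP, float)
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n):
        idx = rng.integers(0, len(pred), len(pred))
        try:
            vals.append(metric_fn(pred[idx], obs[idx]))
        except DegenerateError:
            skipped += 1
    if skipped > n // 2:
        raise DegenerateError(
            f"{skipped}/{n} bootstrap resamples had undefined metric"
        )
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(vals, lo)),
        float(np.quantile(vals, 1.0 - lo)),
    )


def null_model_accuracy(
    obs_cP, class_cutoff: float = VISCOUS_CUTOFF_CP
) -> tuple[float, bool]:
    """Accuracy of always predicting the majority class; (0.5, True) on a tie."""
    obs = np.asarray(obs_cP, float)
    if len(obs) == 0:
        raise DataError("empty observations")
    n_high = int(np.sum(obs >= class_cutoff))
    n_low = len(obs) - n_high
    if n_high == n_low:
        return 0.5, True
    return max(n_high, n_low) / len(obs), False


def metrics_report(
    pred_cP,
    obs_cP,
    class_cutoff: float = VISCOUS_CUTOFF_CP,
    r2_scale: str = "log10",
    n_bootstrap: int = 500,
    seed: int = 0,
    oop_rule: str = "corner",
) -> MetricsReport:
    """Full evaluation with 95% bootstrap CIs for rho, R^2 and AUC."""
    rho, r2 = regression_metrics(pred_cP, obs_cP, scale=r2_scale)
    auc, cutoff, confusion = roc_analysis(
        pred_cP, obs_cP, class_cutoff, oop_rule=oop_rule
    )
    n = len(pred_cP)
    acc = float(np.trace(confusion)) / n
    ci = {
        "spearman": bootstrap_ci(
            lambda p, o: regression_metrics(p, o, scale=r2_scale)[0],
            pred_cP, obs_cP, n_bootstrap, seed,
        ),
        "r2": bootstrap_ci(
            lambda p, o: regression_metrics(p, o, scale=r2_scale)[1],
            pred_cP, obs_cP, n_bootstrap, seed + 1,
        ),
        "roc_auc": bootstrap_ci(
            lambda p, o: roc_analysis(p, o, class_cutoff)[0],
            pred_cP, obs_cP, n_bootstrap, seed + 2,
        ),
    }
    return MetricsReport(
        spearman=rho,
        r2=r2,
        roc_auc=auc,
        oop_cutoff=cutoff,
        confusion=confusion,
        accuracy=acc,
        n=n,
        ci=ci,
        n_bootstrap=n_bootstrap,
        oop_rule=oop_rule,
    )
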