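"""Survival and classification statistics used to evaluate every classifier.

The two-group proportional-hazards fit is deliberately written as a one
dimensional problem: with a binary covariate the Breslow partial likelihood
depends only on per-event-time risk-set counts, so it can be maximized by a
bracketed scalar optimizer and checked against a brute-force grid search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_BETA_BRACKET = 20.0


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood maximizer does not exist (separation)."""


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    beta: float
    se: float


@dataclass
class KMCurve:
    """Product-limit estimate: one row per distinct event time."""

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if not np.isfinite(times).all() or (times <= 0).any():
        raise ValueError("survival times must be positive and finite")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    Censored observations only shrink the risk set; survival rows are
    emitted at distinct event times.
    """
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    n = times.size
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(times >= t))
        d[i] = int(np.sum((times == t) & (events == 1)))
    surv = np.cumprod(1.0 - d / at_risk) if event_times.size else np.empty(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood_terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        var = np.where(surv > 0, surv**2 * np.cumsum(greenwood_terms), 0.0)
    logger.debug("KM estimate: n=%d, %d distinct event times", n, event_times.size)
    return KMCurve(event_times, at_risk, d, surv, var)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test: chi-square on 1 df from observed minus expected."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"logrank_test requires exactly 2 groups, got {levels.size}")
    in1 = groups == levels[1]
    if events.sum() == 0:
        warnings.warn("no events in either group; log-rank statistic is undefined, reporting p=1")
        return 0.0, 1.0
    observed1 = 0.0
    expected1 = 0.0
    variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d_tot = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in1).sum())
        observed1 += d1
        expected1 += d_tot * n1 / n_tot
        if n_tot > 1:
            variance += (
                d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if variance == 0:
        warnings.warn("log-rank variance is zero; reporting p=1")
        return 0.0, 1.0
    statistic = (observed1 - expected1) ** 2 / variance
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def _breslow_counts(times, events, x):
    """Per-distinct-event-time counts for the binary-covariate partial likelihood.

    Sorted cumulative sums keep this O(n log n) so large simulated cohorts
    fit quickly.
    """
    order = np.argsort(times, kind="stable")
    t_s, e_s, x_s = times[order], events[order], x[order]
    event_times = np.unique(t_s[e_s == 1])
    lo = np.searchsorted(t_s, event_times, side="left")
    hi = np.searchsorted(t_s, event_times, side="right")
    suffix_x = np.concatenate([np.cumsum(x_s[::-1])[::-1], [0]])
    n1 = suffix_x[lo].astype(float)
    n0 = (t_s.size - lo) - n1
    cum_e = np.concatenate([[0], np.cumsum(e_s)])
    cum_ex = np.concatenate([[0], np.cumsum(e_s * x_s)])
    d = (cum_e[hi] - cum_e[lo]).astype(float)
    d1 = (cum_ex[hi] - cum_ex[lo]).astype(float)
    return d, d1, n1, n0


def breslow_loglik(beta, d, d1, n1, n0):
    """Breslow-ties log partial likelihood for a binary covariate (vectorized in beta)."""
    beta = np.asarray(beta, dtype=float)
    eb = np.exp(beta)
    denom = np.log(np.outer(eb, n1) + n0[None, :]) if beta.ndim else np.log(eb * n1 + n0)
    if beta.ndim:
        return beta * d1.sum() - (d[None, :] * denom).sum(axis=1)
    return float(beta * d1.sum() - (d * denom).sum())


def cox_binary_hr(times, events, group_indicator) -> HazardRatioResult:
    """Unadjusted proportional-hazards fit of a binary group indicator.

    Maximizes the Breslow partial likelihood over a bracketed interval,
    with the standard error from the observed information, a Wald z
    p-value, and a 95% CI on the log scale.
    """
    times, events = _check_surv(times, events)
    x = np.asarray(group_indicator, dtype=int)
    if not np.isin(x, [0, 1]).all():
        raise ValueError("group_indicator must be binary 0/1")
    if x.min() == x.max():
        raise ValueError("both indicator levels must be present")
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("no events; hazard ratio is undefined")
    d, d1, n1, n0 = _breslow_counts(times, events, x)
    # finite MLE iff the (concave) score changes sign: its beta -> -inf limit
    # must be positive and its beta -> +inf limit negative
    score_lo = d1.sum() - d[n0 == 0].sum()
    score_hi = d1.sum() - d[n1 > 0].sum()
    if score_lo <= 0 or score_hi >= 0:
        raise ConvergenceError(
            "complete separation: the partial likelihood is monotone, the MLE diverges"
        )
    res = optimize.minimize_scalar(
        lambda b: -breslow_loglik(b, d, d1, n1, n0),
        bounds=(-_BETA_BRACKET, _BETA_BRACKET),
        method="bounded",
        options={"xatol": 1e-10},
    )
    beta = float(res.x)
    if abs(beta) > _BETA_BRACKET - 1e-3:
        raise ConvergenceError(f"estimate at bracket boundary (beta={beta:.3f})")
    eb = np.exp(beta)
    info = float(np.sum(d * n1 * n0 * eb / (n1 * eb + n0) ** 2))
    if info <= 0:
        raise ConvergenceError("singular observed information")
    se = info**-0.5
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return HazardRatioResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(p),
        n=int(times.size),
        events=n_events,
        beta=beta,
        se=float(se),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(probabilities, death_labels) -> ROCResult:
    """ROC curve and AUC with death (poor prognosis) as the positive class.

    AUC equals the probability that a random positive outranks a random
    negative, with ties counted one half.
    """
    probs = np.asarray(probabilities, dtype=float)
    labels = np.asarray(death_labels, dtype=int)
    if np.unique(labels).size != 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thresholds = roc_curve(labels, probs, pos_label=1)
    auc = float(roc_auc_score(labels, probs))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def confusion_metrics(predicted_poor, death_labels) -> ConfusionMetrics:
    """Confusion counts with death-within-horizon as the positive class.

    A patient who died is a TP when called poor prognosis and an FN when
    called good; a survivor is a TN when called good and an FP when called
    poor.
    """
    pred = np.asarray(predicted_poor, dtype=int)
    truth = np.asarray(death_labels, dtype=int)
    if pred.size == 0:
        raise ValueError("empty predictions")
    if pred.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / pred.size
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, acc)


def compare_log2_hr_paired(hr_list_a, hr_list_b) -> PairedTResult:
    """Paired t-test on log2-transformed hazard ratios."""
    a = np.asarray(hr_list_a, dtype=float)
    b = np.asarray(hr_list_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length HR lists with n >= 2")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("hazard ratios must be positive")
    diff = np.log2(a) - np.log2(b)
    sd = diff.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance paired differences; t-test is degenerate")
        return PairedTResult(t=float("nan"), df=a.size - 1, p=float("nan"), degenerate=True)
    t = diff.mean() / (sd / np.sqrt(a.size))
    p = 2.0 * stats.t.sf(abs(t), df=a.size - 1)
    return PairedTResult(t=float(t), df=a.size - 1, p=float(p), degenerate=False)
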