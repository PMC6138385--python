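"""Assembling and serializing classifier evaluation reports.

A report bundles the unadjusted hazard ratio, log-rank test, confusion
metrics, optional AUC and the per-group Kaplan-Meier curves for one
classifier.  Reports serialize to JSON (deterministic: sorted keys, no
timestamps) with the KM curves written as companion TSV tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import survstats
from .classify import make_binary_outcome
from .survstats import ConfusionMetrics, HazardRatioResult, KMCurve

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    classifier: str
    hr: HazardRatioResult | None = None
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    auc: float | None = None
    confusion: ConfusionMetrics | None = None
    n_patients: int = 0
    n_unclassified: int = 0
    seed: int | None = None
    config_digest: str | None = None
    km_curves: dict[str, KMCurve] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return self.hr is None and self.confusion is None and self.auc is None


def evaluate_classifier(
    predicted_poor: pd.Series,
    survival: pd.DataFrame,
    horizon_years: float = 5.0,
    poor_probability: pd.Series | None = None,
    classifier: str = "classifier",
    seed: int | None = None,
    config_digest: str | None = None,
) -> EvaluationReport:
    """Full evaluation of binary poor-prognosis calls against survival data.

    ``predicted_poor`` holds 0/1 calls (1 = poor prognosis); patients with
    NaN (e.g. unanimous-classifier abstentions) are excluded and counted as
    unclassified.  KM, log-rank and HR compare poor vs good; confusion and
    AUC use the death-by-horizon label as the positive class.
    """
    preds = predicted_poor.dropna()
    n_unclassified = int(predicted_poor.isna().sum())
    common = preds.index.intersection(survival.index)
    preds = preds.loc[common].astype(int)
    surv = survival.loc[common]
    if preds.empty:
        raise ValueError("no classified patients to evaluate")

    times = surv["time_years"].to_numpy()
    events = surv["event"].to_numpy().astype(int)
    groups = preds.to_numpy()

    report = EvaluationReport(
        classifier=classifier,
        n_patients=len(preds),
        n_unclassified=n_unclassified,
        seed=seed,
        config_digest=config_digest,
    )
    if np.unique(groups).size == 2 and events.sum() > 0:
        try:
            report.hr = survstats.cox_binary_hr(times, events, groups)
        except survstats.ConvergenceError as exc:
            logger.warning("%s: hazard ratio not estimable (%s)", classifier, exc)
        stat, p = survstats.logrank_test(times, events, groups)
        report.logrank_statistic, report.logrank_p = stat, p
    else:
        logger.warning("%s: single risk group or no events; skipping HR/log-rank", classifier)

    deaths = 1 - make_binary_outcome(surv, horizon_years).to_numpy()
    report.confusion = survstats.confusion_metrics(groups, deaths)
    if poor_probability is not None and np.unique(deaths).size == 2:
        probs = poor_probability.loc[common].to_numpy(dtype=float)
        report.auc = survstats.roc_auc(probs, deaths).auc
    for label, mask in (("poor", groups == 1), ("good", groups == 0)):
        if mask.any():
            report.km_curves[label] = survstats.km_estimate(times[mask], events[mask])
    return report


def _km_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.times,
            "at_risk": curve.at_risk,
            "n_events": curve.n_events,
            "survival": curve.survival,
            "greenwood_variance": curve.variance,
        }
    )


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write the report JSON plus one ``<stem>_km_<group>.tsv`` per KM curve."""
    if report.is_empty():
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    payload: dict = {
        "classifier": report.classifier,
        "n_patients": report.n_patients,
        "n_unclassified": report.n_unclassified,
        "provenance": {"seed": report.seed, "config_digest": report.config_digest},
    }
    if report.hr is not None:
        payload["hazard_ratio"] = {
            "hr": report.hr.hr,
            "ci_low": report.hr.ci_low,
            "ci_high": report.hr.ci_high,
            "p": report.hr.p,
            "n": report.hr.n,
            "events": report.hr.events,
        }
    if report.logrank_statistic is not None:
        payload["logrank"] = {"statistic": report.logrank_statistic, "p": report.logrank_p}
    if report.auc is not None:
        payload["auc"] = report.auc
    if report.confusion is not None:
        c = report.confusion
        payload["confusion"] = {
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "sensitivity": c.sensitivity, "specificity": c.specificity,
            "accuracy": c.accuracy,
        }
    payload["km_tables"] = {}
    for group, curve in report.km_curves.items():
        km_path = path.with_name(f"{path.stem}_km_{group}.tsv")
        _km_frame(curve).to_csv(km_path, sep="\t", index=False)
        payload["km_tables"][group] = km_path.name
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    logger.info("wrote report %s", path)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
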