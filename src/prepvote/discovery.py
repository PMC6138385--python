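"""De novo prognostic signature discovery and the meta-ensemble.

Per pipeline variant: median dichotomize every gene, scan each with an
unadjusted two-group proportional-hazards fit, FDR-adjust the Wald
p-values, keep the top-ranked significant genes as that pipeline's
signature, validate each signature with a cross-validated tree-ensemble
classifier, and stack the per-pipeline classifications in a second-level
(meta) tree ensemble.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierResult, TreeEnsemble, tune_grid
from .config import stage_seed
from .scoring import GeneSignature, median_dichotomize
from .survstats import ConvergenceError, bh_adjust, cox_binary_hr

logger = logging.getLogger(__name__)


def per_gene_cox_scan(matrix: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    """Univariate hazard scan: one dichotomized proportional-hazards fit per gene.

    Returns a DataFrame with columns gene_id, beta, hr, wald_p,
    fdr_adjusted_p, rank — ranked by ascending adjusted then raw p.
    Constant genes (or genes with a degenerate fit) are skipped with a
    warning.
    """
    patients = [p for p in matrix.columns if p in survival.index]
    if not patients:
        raise ValueError("no overlap between matrix patients and survival table")
    surv = survival.loc[patients]
    times = surv["time_years"].to_numpy()
    events = surv["event"].to_numpy().astype(int)
    if events.sum() == 0:
        raise ValueError("no events in the cohort; scan is undefined")
    values = matrix[patients]

    rows = []
    skipped = 0
    for gene in values.index:
        row = values.loc[gene].to_numpy(dtype=float)
        if np.ptp(row) == 0:
            skipped += 1
            continue
        groups = median_dichotomize(row)
        if groups.min() == groups.max():
            skipped += 1
            continue
        try:
            fit = cox_binary_hr(times, events, groups)
        except (ConvergenceError, ValueError):
            skipped += 1
            continue
        rows.append((gene, fit.beta, fit.hr, fit.p))
    if skipped:
        warnings.warn(f"skipped {skipped} constant or degenerate genes in hazard scan")
    if not rows:
        raise ValueError("no testable genes in matrix")
    scan = pd.DataFrame(rows, columns=["gene_id", "beta", "hr", "wald_p"])
    scan["fdr_adjusted_p"] = bh_adjust(scan["wald_p"].to_numpy())
    scan = scan.sort_values(
        ["fdr_adjusted_p", "wald_p", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    scan["rank"] = np.arange(1, len(scan) + 1)
    return scan


def select_top_genes(
    scan: pd.DataFrame, top_k: int = 100, alpha: float = 0.05, name: str = "novel"
) -> GeneSignature:
    """Top-ranked genes with adjusted p below ``alpha``, truncated to ``top_k``."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    passing = scan[scan["fdr_adjusted_p"] < alpha]
    if passing.empty:
        raise ValueError(f"no genes pass FDR < {alpha}")
    if len(passing) < top_k:
        warnings.warn(
            f"only {len(passing)} genes pass FDR < {alpha} (requested {top_k}); keeping all"
        )
    chosen = passing.nsmallest(top_k, "rank") if len(passing) > top_k else passing
    return GeneSignature(name=name, genes=tuple(chosen.sort_values("rank")["gene_id"]))


def cross_validated_signature_classifier(
    matrix: pd.DataFrame,
    signature: GeneSignature,
    outcome: pd.Series,
    folds: int = 10,
    seed: int = 0,
    mtry: int | None = None,
    ntree: int = 500,
) -> pd.DataFrame:
    """Stratified k-fold out-of-fold predictions from signature-gene features.

    Features are the cohort-median-dichotomized signature genes.  Every
    patient receives exactly one held-out prediction.  Returns a DataFrame
    indexed by patient with columns ``predicted`` (alive-at-horizon scale)
    and ``poor_probability``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    patients = [p for p in matrix.columns if p in outcome.index]
    genes = [g for g in signature.genes if g in matrix.index]
    if not genes:
        raise ValueError(f"no signature genes present in matrix for {signature.name!r}")
    y = outcome.loc[patients]
    if y.value_counts().min() < folds:
        raise ValueError("a class is too rare for stratified cross-validation")
    block = matrix.loc[genes, patients].to_numpy(dtype=float)
    X = (block > np.median(block, axis=1, keepdims=True)).astype(float).T  # patients x genes
    y_arr = y.to_numpy()
    if mtry is None:
        mtry = max(1, int(np.sqrt(X.shape[1])))

    predicted = np.empty(len(patients), dtype=int)
    poor_prob = np.empty(len(patients), dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=stage_seed(seed, "cv") % 2**32)
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y_arr)):
        model = TreeEnsemble(mtry, ntree, seed=stage_seed(seed, "cv-fold", k))
        model.fit(X[train_idx], y_arr[train_idx])
        proba = model.predict_proba(X[test_idx])
        poor_col = int(np.flatnonzero(model.classes_ == 0)[0])
        pp = proba[:, poor_col]
        poor_prob[test_idx] = pp
        predicted[test_idx] = np.where(pp > 0.5, 0, 1)
    return pd.DataFrame(
        {"predicted": predicted, "poor_probability": poor_prob},
        index=pd.Index(patients, name="patient_id"),
    )


def meta_ensemble(
    classifications_by_pipeline: pd.DataFrame,
    outcome: pd.Series,
    partition: tuple[pd.Index, pd.Index],
    mtry_grid=(1, 2, 4),
    ntree_grid=(500,),
    seed: int = 0,
) -> ClassifierResult:
    """Second-level tuned ensemble over per-pipeline good/poor classifications."""
    if classifications_by_pipeline.shape[1] < 2:
        raise ValueError("meta-ensemble needs at least 2 pipeline classification columns")
    return tune_grid(
        classifications_by_pipeline,
        outcome,
        partition,
        mtry_grid,
        ntree_grid,
        seed=seed,
        feature_set="meta",
    )


def subtype_accuracy(
    predictions: pd.Series, outcome: pd.Series, subtypes: pd.Series
) -> pd.DataFrame:
    """Classification accuracy within each subtype label.

    Patients without a subtype label are excluded from every subtype row;
    the ``overall`` row covers all labeled patients.  Empty groups report
    missing (NaN) accuracy.
    """
    common = predictions.index.intersection(outcome.index)
    pred = predictions.loc[common]
    truth = outcome.loc[common]
    labels = subtypes.reindex(common)
    labeled = labels.notna()
    rows = []
    for subtype in sorted(labels.dropna().unique()):
        mask = labels == subtype
        n = int(mask.sum())
        acc = float((pred[mask] == truth[mask]).mean()) if n else float("nan")
        rows.append((subtype, n, acc))
    n_lab = int(labeled.sum())
    overall = float((pred[labeled] == truth[labeled]).mean()) if n_lab else float("nan")
    rows.append(("overall", n_lab, overall))
    return pd.DataFrame(rows, columns=["subtype", "n", "accuracy"]).set_index("subtype")
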