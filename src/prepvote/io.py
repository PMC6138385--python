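"""Readers and writers for the tab-delimited interchange formats.

All tables are plain TSV: abundance matrices are genes x patients with the
gene id in the first column, clinical tables are one row per patient, vote
matrices are patients x pipeline ids, and signature files hold one gene id
per line ('#' starts a comment).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("patient_id", "dataset_id", "time_years", "event")


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x patients abundance matrix.

    Returns a float DataFrame indexed by gene id with patient ids as
    columns.  Duplicated gene ids, duplicated patient ids, missing or
    non-numeric cells, and ragged rows are all rejected with an error that
    names the offending row.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate patient ids: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gene = bad.any(axis=1).idxmax()
        patient = bad.loc[gene].idxmax()
        raise ValueError(
            f"{path}: non-numeric or missing value for gene {gene!r}, patient {patient!r}"
        )
    logger.info("read abundance matrix %s: %d genes x %d patients", path, *numeric.shape)
    return numeric.astype(float)


def write_abundance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical annotation table into a patient-indexed DataFrame.

    Required columns: patient_id, dataset_id, time_years, event; an optional
    ``subtype`` column is carried through (empty cells become NaN).
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "dataset_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient ids: {dupes}")
    times = pd.to_numeric(df["time_years"], errors="raise")
    if (times <= 0).any() or not np.isfinite(times).all():
        bad = df.loc[~(times > 0), "patient_id"].tolist()
        raise ValueError(f"{path}: non-positive survival time for patients {bad}")
    events = pd.to_numeric(df["event"], errors="raise")
    if not events.isin([0, 1]).all():
        bad = df.loc[~events.isin([0, 1]), "patient_id"].tolist()
        raise ValueError(f"{path}: event indicator outside {{0,1}} for patients {bad}")
    out = df.set_index("patient_id")
    out["time_years"] = times.to_numpy(dtype=float)
    out["event"] = events.to_numpy(dtype=int)
    if "subtype" not in out.columns:
        out["subtype"] = pd.Series(pd.NA, index=out.index, dtype="string")
    else:
        out["subtype"] = out["subtype"].astype("string")
    logger.info("read clinical table %s: %d patients", path, len(out))
    return out[["dataset_id", "time_years", "event", "subtype"]]


def write_clinical(survival: pd.DataFrame, path: str | Path) -> None:
    survival.to_csv(path, sep="\t", index_label="patient_id")


def read_signature(path: str | Path, name: str | None = None):
    """Read a gene signature file: one gene id per line, '#' comments allowed."""
    from .scoring import GeneSignature

    genes: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return GeneSignature(name=name or Path(path).stem, genes=tuple(genes))


def write_signature(signature, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in signature.genes))


def read_vote_matrix(path: str | Path) -> pd.DataFrame:
    votes = pd.read_csv(path, sep="\t", index_col=0)
    if not votes.isin([0, 1]).all().all():
        raise ValueError(f"{path}: vote matrix entries must be 0/1")
    return votes.astype(np.int8)


def write_vote_matrix(votes: pd.DataFrame, path: str | Path) -> None:
    votes.to_csv(path, sep="\t", index_label="patient_id")
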