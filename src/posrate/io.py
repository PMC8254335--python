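"""Tab-separated readers and writers for expression, sample, survival and
annotation tables.

All files are UTF-8 TSV with '.' decimal points. Expression matrices carry
gene identifiers in the first column and sample identifiers in the header
row (``orientation="samples_in_rows"`` transposes on read). Readers are
pure: the same file always yields the same in-memory object. Every
exclusion rule logs the number of rows it removed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .types import (
    GeneAnnotation,
    LabeledExpressionDataset,
    Pair,
    PairedExpressionCohort,
    SurvivalCohort,
)

logger = logging.getLogger("posrate")

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "read_survival_table",
    "write_survival_table",
    "read_annotation",
    "load_paired_cohort",
    "load_labeled_dataset",
]


def read_expression_matrix(
    path,
    orientation: Literal["genes_in_rows", "samples_in_rows"] = "genes_in_rows",
    duplicate_policy: Literal["max-mean", "error"] = "max-mean",
    missing_policy: Literal["error", "drop-genes"] = "error",
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Read a log2 expression matrix (genes x samples).

    Parameters
    ----------
    duplicate_policy : {"max-mean", "error"}
        "max-mean" keeps, per duplicated gene id, the row with the highest
        mean expression (a deterministic probe-collapse policy).
    missing_policy : {"error", "drop-genes"}
        "drop-genes" deletes genes with any missing value and logs the count.
    log2_transform : bool
        Apply log2(x + 1) to raw (count-scale) input. Off by default: input
        is assumed to be log2 already.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample identifiers: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    if orientation == "samples_in_rows":
        df = df.T
    # locate any non-numeric cell precisely before coercing
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    df.index = df.index.astype(str)

    if df.index.has_duplicates:
        if duplicate_policy == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:10]}")
        before = len(df)
        order = df.mean(axis=1).to_numpy()
        keep = (
            pd.DataFrame({"_mean": order}, index=df.index)
            .reset_index(names="_gene")
            .sort_values(["_gene", "_mean"], kind="stable")
            .drop_duplicates("_gene", keep="last")
            .index
        )
        df = df.iloc[sorted(keep)]
        logger.info("collapsed %d duplicate gene rows (max-mean policy)", before - len(df))

    if df.isna().any().any():
        if missing_policy == "error":
            raise ValueError("missing expression values (set missing_policy='drop-genes' to delete)")
        before = len(df)
        df = df.dropna(axis=0)
        logger.info("dropped %d genes with missing values", before - len(df))

    if log2_transform:
        df = np.log2(df + 1.0)
    logger.info("read expression matrix %s: %d genes x %d samples", path, *df.shape)
    return df


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", encoding="utf-8")


def read_sample_table(path) -> pd.DataFrame:
    """Read a sample table with columns sample_id, subject_id, tissue.

    ``tissue`` is 'tumor'/'adjacent' for paired designs or 'tumor'/'normal'
    for labeled designs. Returns the validated table; use
    :func:`load_paired_cohort` / :func:`load_labeled_dataset` to assemble a
    cohort object against a matrix.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    required = {"sample_id", "tissue"}
    if not required <= set(df.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    tissues = set(df["tissue"].unique())
    if not (tissues <= {"tumor", "adjacent"} or tissues <= {"tumor", "normal"}):
        raise ValueError(f"tissue labels must be tumor/adjacent or tumor/normal, got {sorted(tissues)}")
    return df


def _pairs_from_table(table: pd.DataFrame) -> list[Pair]:
    if "subject_id" not in table.columns:
        raise ValueError("paired design requires a subject_id column")
    pairs = []
    for subject, grp in table.groupby("subject_id", sort=True):
        tum = grp.loc[grp["tissue"] == "tumor", "sample_id"].tolist()
        adj = grp.loc[grp["tissue"] == "adjacent", "sample_id"].tolist()
        if len(tum) != 1 or len(adj) != 1:
            raise ValueError(
                f"subject {subject!r} must have exactly one tumor and one adjacent sample "
                f"(found {len(tum)} tumor, {len(adj)} adjacent)"
            )
        pairs.append(Pair(str(subject), tum[0], adj[0]))
    return pairs


def load_paired_cohort(matrix_path, samples_path, cohort_id: str, **reader_kwargs) -> PairedExpressionCohort:
    """Assemble a paired cohort from a matrix TSV and a sample TSV."""
    expr = read_expression_matrix(matrix_path, **reader_kwargs)
    table = read_sample_table(samples_path)
    missing = [s for s in table["sample_id"] if s not in expr.columns]
    if missing:
        raise ValueError(f"sample ids absent from matrix: {missing}")
    return PairedExpressionCohort(cohort_id, expr, _pairs_from_table(table))


def load_labeled_dataset(matrix_path, samples_path, dataset_id: str, **reader_kwargs) -> LabeledExpressionDataset:
    """Assemble an unpaired tumor/normal dataset from a matrix TSV and a sample TSV."""
    expr = read_expression_matrix(matrix_path, **reader_kwargs)
    table = read_sample_table(samples_path)
    missing = [s for s in table["sample_id"] if s not in expr.columns]
    if missing:
        raise ValueError(f"sample ids absent from matrix: {missing}")
    labels = pd.Series(table["tissue"].to_numpy(), index=table["sample_id"].to_numpy())
    return LabeledExpressionDataset(dataset_id, expr, labels)


_RESERVED_SURVIVAL = ("patient_id", "time", "event")


def read_survival_table(path, expression: pd.DataFrame | None = None) -> SurvivalCohort:
    """Read a survival table (patient_id, time, event, optional covariates).

    Rows with missing time or event are dropped and counted in the log —
    patients without overall-survival data are excluded from every survival
    analysis. ``expression``, if given, is a genes x patients matrix whose
    columns are matched to the retained patients.
    """
    df = pd.read_csv(path, sep="\t", encoding="utf-8", float_precision="round_trip")
    if not set(_RESERVED_SURVIVAL) <= set(df.columns):
        raise ValueError(f"survival table must have columns {_RESERVED_SURVIVAL}")
    before = len(df)
    df = df.dropna(subset=["time", "event"])
    dropped = before - len(df)
    if dropped:
        logger.info("excluded %d patients without overall-survival data", dropped)
    time = pd.to_numeric(df["time"], errors="raise").to_numpy(dtype=float)
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    event = pd.to_numeric(df["event"], errors="raise").to_numpy(dtype=float)
    if not np.isin(event, (0.0, 1.0)).all():
        raise ValueError("event indicator must be 0 or 1")
    patients = df["patient_id"].astype(str).tolist()
    covars = df.drop(columns=list(_RESERVED_SURVIVAL))
    covars.index = pd.Index(patients)
    expr = None
    if expression is not None:
        missing = [p for p in patients if p not in expression.columns]
        if missing:
            raise ValueError(f"patients absent from expression matrix: {missing[:10]}")
        expr = expression[patients].T
    return SurvivalCohort(
        patient_id=patients,
        time=time,
        event=event.astype(int),
        expression=expr,
        covariates=covars if covars.shape[1] else None,
    )


def write_survival_table(cohort: SurvivalCohort, path) -> None:
    df = pd.DataFrame(
        {"patient_id": cohort.patient_id, "time": cohort.time, "event": cohort.event}
    )
    if cohort.covariates is not None:
        df = pd.concat([df.set_index("patient_id"), cohort.covariates], axis=1).reset_index(
            names="patient_id"
        )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_annotation(path) -> GeneAnnotation:
    """Read a two-column gene_id<TAB>term_id table (one term per line).

    A gene listed with an empty term field is recorded as annotated with no
    terms, which is distinct from a gene absent from the table.
    """
    mapping: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2):
                raise ValueError(f"annotation line {lineno}: expected gene_id<TAB>term_id")
            gene = parts[0]
            mapping.setdefault(gene, set())
            if len(parts) == 2 and parts[1]:
                mapping[gene].add(parts[1])
    logger.info("read annotation for %d genes from %s", len(mapping), path)
    return GeneAnnotation(mapping)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(annotation._terms):
            terms = sorted(annotation._terms[gene])
            if not terms:
                fh.write(f"{gene}\n")
            for t in terms:
                fh.write(f"{gene}\t{t}\n")


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
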