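"""Positive-rate biomarker screening.

The ranking statistic is the *positive rate*: the fraction of paired
subjects in which a gene's tumor expression strictly exceeds its paired
adjacent-tissue expression. A good blood biomarker should be elevated in
nearly every patient, not merely elevated on average, so genes are ranked
by this rate rather than by fold change. The screen keeps the top fraction
of genes per cohort, intersects the per-cohort selections, and finally
restricts to genes annotated to the extracellular region (secreted, hence
plausibly blood-detectable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import EXTRACELLULAR_REGION, GeneAnnotation, PairedExpressionCohort

logger = logging.getLogger("posrate")

__all__ = [
    "compute_positive_rates",
    "select_top_fraction",
    "intersect_candidates",
    "filter_extracellular",
    "run_positive_rate_screen",
    "CandidateSet",
    "ExtracellularFilterReport",
]


@dataclass
class CandidateSet:
    """An ordered candidate gene list with screening provenance."""

    genes: list[str]
    cohort_ids: list[str] = field(default_factory=list)
    selection_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("candidate genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class ExtracellularFilterReport:
    """Bookkeeping for the annotation filter: why each gene was dropped."""

    kept: list[str]
    non_matching: list[str]
    unannotated: list[str]


def compute_positive_rates(cohort: PairedExpressionCohort) -> pd.DataFrame:
    """Per-gene positive counts, rates and mean paired differences.

    A pair counts as positive for a gene when the tumor value is *strictly*
    greater than the adjacent value; ties count as not positive. Returns a
    DataFrame indexed by gene with columns ``positive_count``, ``n_pairs``,
    ``positive_rate``, ``mean_paired_diff`` and ``rank`` (1 = highest rate,
    ties resolved by mean_paired_diff descending then gene id ascending).
    """
    if cohort.n_pairs == 0:
        raise ValueError("cohort has zero pairs")
    diffs = cohort.paired_differences()
    pos = (diffs > 0).sum(axis=1)
    n = cohort.n_pairs
    table = pd.DataFrame(
        {
            "positive_count": pos.astype(int),
            "n_pairs": n,
            "positive_rate": pos / n,
            "mean_paired_diff": diffs.mean(axis=1),
        },
        index=pd.Index(cohort.genes, name="gene_id"),
    )
    order = table.sort_values(
        ["positive_rate", "mean_paired_diff", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
    ).index
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    table["rank"] = table["rank"].astype(int)
    return table


def select_top_fraction(table: pd.DataFrame, q: float) -> list[str]:
    """Genes in the top fraction ``q`` by positive rate.

    Returns exactly ``ceil(q * G)`` genes in rank order. The ceiling
    guarantees a non-empty selection and matches cohort-scale counts such
    as 1070 genes from a ~21,400-gene array at q = 0.05.
    """
    if len(table) == 0:
        raise ValueError("empty positive-rate table")
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    k = math.ceil(q * len(table))
    return table.sort_values("rank").index[:k].tolist()


def intersect_candidates(selections: list[list[str]], cohort_ids: list[str] | None = None) -> CandidateSet:
    """Genes selected in *every* cohort, ordered by mean rank across cohorts.

    The rank of a gene within a cohort is its position in that cohort's
    selection list; genes with equal mean rank are ordered by gene id. An
    empty intersection is a valid result.
    """
    if len(selections) < 2:
        raise ValueError("need at least two per-cohort selections to intersect")
    if cohort_ids is None:
        cohort_ids = [f"cohort_{i}" for i in range(len(selections))]
    common = set(selections[0])
    for sel in selections[1:]:
        common &= set(sel)
    mean_rank = {
        g: float(np.mean([sel.index(g) for sel in selections])) for g in common
    }
    ordered = sorted(common, key=lambda g: (mean_rank[g], g))
    return CandidateSet(
        genes=ordered,
        cohort_ids=list(cohort_ids),
        selection_sizes={cid: len(sel) for cid, sel in zip(cohort_ids, selections)},
    )


def filter_extracellular(
    candidates: CandidateSet,
    annotation: GeneAnnotation,
    target_terms: set[str] | None = None,
) -> tuple[CandidateSet, ExtracellularFilterReport]:
    """Restrict candidates to genes annotated with a target cellular component.

    Unannotated genes are dropped and reported separately from genes that
    are annotated but match none of the target terms.
    """
    terms = {EXTRACELLULAR_REGION} if target_terms is None else set(target_terms)
    if not terms:
        raise ValueError("target_terms must be non-empty")
    kept, non_matching, unannotated = [], [], []
    for gene in candidates.genes:
        if gene not in annotation:
            unannotated.append(gene)
        elif annotation.matches(gene, terms):
            kept.append(gene)
        else:
            non_matching.append(gene)
    logger.info(
        "extracellular filter: kept %d, dropped %d non-matching, %d unannotated",
        len(kept), len(non_matching), len(unannotated),
    )
    report = ExtracellularFilterReport(kept, non_matching, unannotated)
    filtered = CandidateSet(
        genes=kept,
        cohort_ids=candidates.cohort_ids,
        selection_sizes=dict(candidates.selection_sizes),
    )
    return filtered, report


def run_positive_rate_screen(
    cohorts: list[PairedExpressionCohort],
    annotation: GeneAnnotation | None = None,
    top_fraction: float = 0.05,
    target_terms: set[str] | None = None,
) -> dict:
    """Full screen: positive rates -> top fraction per cohort -> intersection
    -> optional extracellular filter.

    Returns a dict with per-cohort rate tables and selections, the
    intersection, and (if an annotation is given) the filtered candidate set
    and filter report.
    """
    tables = {c.cohort_id: compute_positive_rates(c) for c in cohorts}
    selections = {cid: select_top_fraction(t, top_fraction) for cid, t in tables.items()}
    intersection = intersect_candidates(list(selections.values()), list(selections.keys()))
    out = {
        "rate_tables": tables,
        "selections": selections,
        "intersection": intersection,
    }
    if annotation is not None:
        filtered, report = filter_extracellular(intersection, annotation, target_terms)
        out["candidates"] = filtered
        out["filter_report"] = report
    return out
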