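"""Fold-change differential-expression screen, the conventional baseline.

The comparison pipeline: per-cohort paired t-tests on tumor - adjacent
log2 differences, a tumor-high fold-change gate (FC > 2, i.e. mean log2
difference > 1) combined with a Benjamini–Hochberg adjusted-p gate,
cross-cohort intersection and the same extracellular filter as the
positive-rate screen. Because the gate sits on the *mean* difference, it
overlooks genes with a small but near-universal shift — the scenario the
positive-rate statistic is designed to catch; ``compare_screens`` measures
that contrast on planted-truth data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screening import CandidateSet, filter_extracellular, intersect_candidates
from .types import AnalysisConfig, GeneAnnotation, PairedExpressionCohort

logger = logging.getLogger("posrate")

__all__ = ["paired_de_test", "run_deg_screen", "compare_screens"]


def paired_de_test(cohort: PairedExpressionCohort) -> pd.DataFrame:
    """Per-gene paired differential expression.

    Returns a DataFrame indexed by gene with ``log2fc`` (mean tumor -
    adjacent log2 difference), ``p`` (two-sided paired t-test), ``p_adj``
    (Benjamini–Hochberg across the cohort's genes) and ``zero_variance``
    (genes whose differences are constant get p = 1 and a flag instead of
    an undefined statistic).
    """
    if cohort.n_pairs < 3:
        raise ValueError("paired differential expression needs at least 3 pairs")
    diffs = cohort.paired_differences()
    log2fc = diffs.mean(axis=1)
    zero_var = np.ptp(diffs, axis=1) == 0
    with np.errstate(all="ignore"):
        res = stats.ttest_1samp(diffs, 0.0, axis=1)
    p = np.where(zero_var, 1.0, res.pvalue)
    p_adj = multipletests(p, method="fdr_bh")[1]
    if zero_var.any():
        logger.info("%d genes with zero-variance differences flagged (p set to 1)", int(zero_var.sum()))
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": p_adj, "zero_variance": zero_var},
        index=pd.Index(cohort.genes, name="gene_id"),
    )


def run_deg_screen(
    cohorts: list[PairedExpressionCohort],
    annotation: GeneAnnotation | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Full fold-change screen across cohorts, parallel to the
    positive-rate screen.

    A gene is a DEG in a cohort when its tumor-high log2 fold change
    exceeds log2(fc_threshold) and its BH-adjusted p is below
    adj_p_threshold. DEG sets are intersected and, if an annotation is
    given, extracellularly filtered.
    """
    if not cohorts:
        raise ValueError("empty cohort list")
    config = config or AnalysisConfig()
    log2_cut = np.log2(config.fc_threshold)
    tables = {}
    selections = {}
    for cohort in cohorts:
        table = paired_de_test(cohort)
        mask = (table["log2fc"] > log2_cut) & (table["p_adj"] < config.adj_p_threshold)
        # order by significance so the intersection's mean-rank ordering is meaningful
        degs = table[mask].sort_values(["p_adj", "p"]).index.tolist()
        tables[cohort.cohort_id] = table
        selections[cohort.cohort_id] = degs
        logger.info("cohort %s: %d DEGs (FC > %.3g, adj p < %.3g)",
                    cohort.cohort_id, len(degs), config.fc_threshold, config.adj_p_threshold)
    nonempty = all(len(s) > 0 for s in selections.values())
    if len(selections) >= 2 and nonempty:
        intersection = intersect_candidates(list(selections.values()), list(selections.keys()))
    else:
        intersection = CandidateSet([], list(selections.keys()),
                                    {c: len(s) for c, s in selections.items()})
    out = {"de_tables": tables, "selections": selections, "intersection": intersection}
    if annotation is not None:
        filtered, report = filter_extracellular(intersection, annotation, set(config.extracellular_terms))
        out["candidates"] = filtered
        out["filter_report"] = report
    return out


def compare_screens(
    positive_rate_genes: list[str],
    deg_genes: list[str],
    planted_genes: list[str],
) -> dict:
    """Head-to-head sensitivity of the two screens against planted truth.

    Sensitivity = planted genes recovered / planted. Returns both
    sensitivities, their difference (positive-rate minus fold-change) and
    the overlap of the two recovered sets.
    """
    planted = set(planted_genes)
    if not planted:
        raise ValueError("no planted genes to score against")
    pr = set(positive_rate_genes) & planted
    de = set(deg_genes) & planted
    return {
        "positive_rate_sensitivity": len(pr) / len(planted),
        "deg_sensitivity": len(de) / len(planted),
        "sensitivity_gap": (len(pr) - len(de)) / len(planted),
        "overlap": sorted(pr & de),
    }
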