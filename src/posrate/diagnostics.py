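"""Per-gene diagnostic ROC analysis and the multi-dataset AUC gate.

The AUC here is the probability that a randomly chosen tumor sample's
marker value exceeds a randomly chosen normal sample's (ties count one
half) — the Mann–Whitney formulation. Orientation is fixed tumor-high:
markers that run the other way earn AUC < 0.5 and simply fail the gate;
nothing is auto-flipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .types import LabeledExpressionDataset

logger = logging.getLogger("posrate")

__all__ = ["RocResult", "roc_auc", "validate_candidates"]


@dataclass
class RocResult:
    """Empirical ROC summary for one marker.

    ``curve`` is the ordered list of (1 - specificity, sensitivity) points
    from (0, 0) to (1, 1); ``youden_cutoff`` is an attained marker value
    maximizing sensitivity + specificity - 1 (ties broken toward higher
    specificity), with the classification rule value >= cutoff -> tumor.
    """

    auc: float
    se: float
    ci95: tuple[float, float]
    curve: np.ndarray  # (k, 2) array of (fpr, tpr)
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float

    @property
    def youden_index(self) -> float:
        return self.sens_at_cutoff + self.spec_at_cutoff - 1.0


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    # Hanley & McNeil (1982) asymptotic SE of the empirical AUC.
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(values, labels, positive_label: str = "tumor") -> RocResult:
    """Empirical ROC of one marker against tumor/normal labels.

    ``values`` are per-sample marker levels; ``labels`` the matching class
    labels. Larger values are taken to indicate the positive (tumor) class.
    A constant marker yields AUC 0.5 with a degeneracy warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive_label]
    neg = values[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")

    # Mann-Whitney AUC via midranks: ties contribute one half.
    ranks = rankdata(values)
    r_pos = ranks[labels == positive_label].sum()
    n1, n0 = len(pos), len(neg)
    auc = float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))

    if np.ptp(values) == 0:
        warnings.warn("constant marker: ROC is degenerate, AUC = 0.5", RuntimeWarning)

    y = (labels == positive_label).astype(int)
    fpr, tpr, thresholds = _sk_roc_curve(y, values, drop_intermediate=False)
    curve = np.column_stack([fpr, tpr])

    # Youden-optimal cutoff among attained marker values. sklearn's
    # thresholds[0] is an unattained sentinel above the maximum; skip it.
    # Classification rule: value >= cutoff -> tumor, so sens = tpr and
    # spec = 1 - fpr at each threshold. Ties in J resolve toward higher
    # specificity (the larger cutoff).
    attained = thresholds[1:] if len(thresholds) > 1 else thresholds
    j = (tpr - fpr)[1:] if len(thresholds) > 1 else (tpr - fpr)
    spec = 1.0 - (fpr[1:] if len(thresholds) > 1 else fpr)
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmax(spec[best])]
    cutoff = float(attained[pick])
    sens = float((tpr[1:] if len(thresholds) > 1 else tpr)[pick])
    spec_pick = float(spec[pick])

    se = _hanley_mcneil_se(auc, n1, n0)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return RocResult(
        auc=auc,
        se=se,
        ci95=ci,
        curve=curve,
        youden_cutoff=cutoff,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec_pick,
    )


def validate_candidates(
    candidates: list[str],
    datasets: list[LabeledExpressionDataset],
    threshold: float = 0.6,
) -> tuple[pd.DataFrame, list[str]]:
    """Diagnostic gate: keep genes with AUC strictly above ``threshold`` in
    *every* dataset.

    Genes absent from any dataset are logged and excluded from the gate.
    Returns (per-gene-per-dataset AUC table, surviving gene list in
    candidate order). The gate is strict: a gene at exactly the threshold
    fails.
    """
    if not datasets:
        raise ValueError("need at least one labeled dataset")
    rows = []
    survivors = []
    for gene in candidates:
        missing = [d.dataset_id for d in datasets if gene not in d.expression.index]
        if missing:
            logger.info("candidate %s absent from dataset(s) %s; excluded", gene, missing)
            continue
        passed = True
        for ds in datasets:
            tum, nor = ds.marker_values(gene)
            vals = np.concatenate([tum, nor])
            labs = np.array(["tumor"] * len(tum) + ["normal"] * len(nor))
            res = roc_auc(vals, labs)
            rows.append(
                {
                    "gene_id": gene,
                    "dataset_id": ds.dataset_id,
                    "auc": res.auc,
                    "se": res.se,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "youden_cutoff": res.youden_cutoff,
                    "sensitivity": res.sens_at_cutoff,
                    "specificity": res.spec_at_cutoff,
                }
            )
            if not res.auc > threshold:
                passed = False
        if passed:
            survivors.append(gene)
    table = pd.DataFrame(rows)
    logger.info(
        "diagnostic gate (AUC > %.3g in all %d datasets): %d of %d candidates retained",
        threshold, len(datasets), len(survivors), len(candidates),
    )
    return table, survivors
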