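"""Serum-panel statistics: median splits, 2x2 association tests, group and
paired comparisons, correlation, and the combined panel scores.

Concentrations keep their assay units throughout — AGT and MMP7 in ng/mL,
SERPINH1 in pg/mL — and the weighted panel score deliberately mixes them,
exactly as its defining coefficients were published; no unit normalization
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SerumPanel",
    "ContingencyTable2x2",
    "split_by_median",
    "chi_square_2x2",
    "mann_whitney_u",
    "paired_t_test",
    "pearson_correlation",
    "panel_scores",
    "association_table",
    "DEFAULT_PANEL_WEIGHTS",
]

MARKER_COLUMNS = ("agt_ng_ml", "serpinh1_pg_ml", "mmp7_ng_ml")

# Published risk-model coefficients reused as serum panel weights
# (AGT, SERPINH1, MMP7).
DEFAULT_PANEL_WEIGHTS = (0.180, 0.544, 0.135)

# Clinical category level pairs (reference level, adverse level) used for
# association tables and covariate encoding.
CLINICAL_LEVELS: dict[str, tuple[str, str]] = {
    "tumor_size": ("<=4", ">4"),
    "tumor_invasion": ("T1-T2", "T3-T4"),
    "lymph_node_invasion": ("negative", "positive"),
    "metastasis": ("negative", "positive"),
    "stage": ("I-II", "III-IV"),
    "gender": ("female", "male"),
    "age_group": ("<=65", ">65"),
}


@dataclass
class SerumPanel:
    """Per-subject serum concentrations with group and clinical metadata.

    ``data`` must carry the marker columns ``agt_ng_ml``, ``serpinh1_pg_ml``
    and ``mmp7_ng_ml`` and a ``group`` column in {'control', 'GC'}; optional
    clinical class columns and paired post-operative columns
    (``post_<marker>``) may follow.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in (*MARKER_COLUMNS, "group") if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        bad = set(self.data["group"].unique()) - {"control", "GC"}
        if bad:
            raise ValueError(f"group must be 'control' or 'GC', got {sorted(bad)}")
        conc = self.data[list(MARKER_COLUMNS)]
        if (conc.to_numpy(dtype=float) <= 0).any():
            raise ValueError("concentrations must be strictly positive")

    def gc(self) -> pd.DataFrame:
        return self.data[self.data["group"] == "GC"]

    def controls(self) -> pd.DataFrame:
        return self.data[self.data["group"] == "control"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a clinical-category (rows) by low/high-marker (columns)
    table: a = row1/low, b = row1/high, c = row2/low, d = row2/high."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be at least 1")


def split_by_median(values) -> tuple[pd.Series, float]:
    """Label each subject low/high relative to the median.

    Values strictly above the median are 'high'; values at or below it are
    'low'. Returns (labels, cutoff).
    """
    values = pd.Series(values)
    if len(values) < 2:
        raise ValueError("need at least 2 subjects")
    arr = values.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        raise ValueError("all values identical: median split undefined")
    cutoff = float(values.median())
    labels = pd.Series(np.where(arr > cutoff, "high", "low"), index=values.index)
    return labels, cutoff


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 df, upper-tail p.
    A zero row or column margin leaves the statistic undefined and raises.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero row or column margin")
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / np.prod(margins)
    return float(stat), 1, float(stats.chi2.sf(stat, df=1))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with midrank ties.

    Exact enumeration when both samples are small (< 8) and tie-free,
    otherwise the tie-corrected normal approximation. Returns (U for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(pre, post) -> tuple[float, int, float]:
    """Two-sided paired t-test on post - pre differences.

    Returns (t, df, p); raises when the differences have zero variance.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or len(pre) < 2:
        raise ValueError("pre and post must have equal length >= 2")
    d = post - pre
    if np.ptp(d) == 0:
        raise ValueError("differences have zero variance: paired t undefined")
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), len(d) - 1, float(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with its t-distribution p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def panel_scores(panel: SerumPanel, weights=DEFAULT_PANEL_WEIGHTS) -> pd.DataFrame:
    """Combined panel scores for the GC subjects.

    score1 is the weighted concentration sum (default weights are the
    published risk-model coefficients, applied to the raw mixed-unit
    concentrations); subjects are then split low/high at its median.
    score2 is 'high' when at least two of the three markers are above
    their own medians.
    """
    gc = panel.gc()
    if len(gc) < 2:
        raise ValueError("need at least 2 GC subjects")
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must have length 3")
    conc = gc[list(MARKER_COLUMNS)].astype(float)
    if conc.isna().any().any():
        bad = conc.columns[conc.isna().any()].tolist()
        raise ValueError(f"missing concentrations in columns {bad}")
    score1 = conc.to_numpy() @ w
    out = pd.DataFrame({"score1": score1}, index=gc.index)
    high_counts = np.zeros(len(gc), dtype=int)
    for col in MARKER_COLUMNS:
        labels, _ = split_by_median(conc[col])
        out[f"{col}_level"] = labels
        high_counts += (labels == "high").to_numpy()
    s1_labels, s1_cut = split_by_median(out["score1"])
    out["score1_level"] = s1_labels
    out["score2_level"] = np.where(high_counts >= 2, "high", "low")
    out.attrs["score1_cutoff"] = s1_cut
    return out


def association_table(
    clinical: pd.Series, marker_labels: pd.Series, row_levels: tuple[str, str]
) -> ContingencyTable2x2:
    """Build the 2x2 clinical-category x low/high table on shared subjects."""
    df = pd.DataFrame({"clin": clinical, "marker": marker_labels}).dropna()
    counts = []
    for lvl in row_levels:
        for mk in ("low", "high"):
            counts.append(int(((df["clin"] == lvl) & (df["marker"] == mk)).sum()))
    return ContingencyTable2x2(*counts)
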