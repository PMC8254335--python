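"""Core data model for paired-cohort biomarker analysis.

Expression matrices are stored as :class:`pandas.DataFrame` objects with
gene identifiers as the row index and sample identifiers as columns, on a
log2 scale throughout. Validation happens at construction time so that
downstream statistics can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Pair",
    "PairedExpressionCohort",
    "LabeledExpressionDataset",
    "SurvivalCohort",
    "GeneAnnotation",
    "AnalysisConfig",
]


@dataclass(frozen=True)
class Pair:
    """One subject's (tumor sample, adjacent non-cancer sample) pairing."""

    subject_id: str
    tumor_sample_id: str
    adjacent_sample_id: str


def _check_unique_genes(expression: pd.DataFrame) -> None:
    if expression.index.has_duplicates:
        dups = expression.index[expression.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:10]}")


@dataclass
class PairedExpressionCohort:
    """Log2 expression for subjects contributing one tumor and one adjacent sample.

    Parameters
    ----------
    cohort_id : str
        Label used in reports and provenance records.
    expression : pandas.DataFrame
        Genes x samples log2 matrix. Columns referenced by ``pairs`` must
        exist and contain no missing values.
    pairs : sequence of Pair
        Subject-level pairing. Every sample id may appear in at most one
        pair.
    """

    cohort_id: str
    expression: pd.DataFrame
    pairs: Sequence[Pair]

    def __post_init__(self) -> None:
        self.pairs = [p if isinstance(p, Pair) else Pair(*p) for p in self.pairs]
        if len(self.pairs) < 2:
            raise ValueError("a paired cohort needs at least 2 pairs")
        if self.expression.shape[0] < 1:
            raise ValueError("expression matrix has no genes")
        _check_unique_genes(self.expression)
        seen: set[str] = set()
        cols = set(self.expression.columns)
        for p in self.pairs:
            for sid in (p.tumor_sample_id, p.adjacent_sample_id):
                if sid in seen:
                    raise ValueError(f"sample {sid!r} referenced by more than one pair")
                seen.add(sid)
                if sid not in cols:
                    raise ValueError(f"sample {sid!r} not a column of the expression matrix")
        sub = self.expression[sorted(seen)]
        if sub.isna().any().any():
            raise ValueError("missing values in paired sample columns")

    @property
    def genes(self) -> list[str]:
        return self.expression.index.tolist()

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def tumor_matrix(self) -> np.ndarray:
        """Genes x pairs array of tumor-sample values, in pair order."""
        return self.expression[[p.tumor_sample_id for p in self.pairs]].to_numpy()

    def adjacent_matrix(self) -> np.ndarray:
        """Genes x pairs array of adjacent-sample values, aligned with tumor_matrix."""
        return self.expression[[p.adjacent_sample_id for p in self.pairs]].to_numpy()

    def paired_differences(self) -> np.ndarray:
        """Genes x pairs array of tumor - adjacent log2 differences."""
        return self.tumor_matrix() - self.adjacent_matrix()


@dataclass
class LabeledExpressionDataset:
    """Unpaired log2 expression with per-sample tumor/normal class labels."""

    dataset_id: str
    expression: pd.DataFrame
    labels: pd.Series  # sample id -> {"tumor", "normal"}

    def __post_init__(self) -> None:
        _check_unique_genes(self.expression)
        self.labels = pd.Series(self.labels)
        bad = set(self.labels.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"labels must be 'tumor' or 'normal', got {sorted(bad)}")
        missing = [s for s in self.labels.index if s not in self.expression.columns]
        if missing:
            raise ValueError(f"labeled samples absent from matrix: {missing[:10]}")
        counts = self.labels.value_counts()
        if counts.get("tumor", 0) == 0 or counts.get("normal", 0) == 0:
            raise ValueError("both tumor and normal classes must be non-empty")

    @property
    def genes(self) -> list[str]:
        return self.expression.index.tolist()

    def class_counts(self) -> tuple[int, int]:
        """(n_tumor, n_normal)."""
        vc = self.labels.value_counts()
        return int(vc["tumor"]), int(vc["normal"])

    def marker_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """(tumor values, normal values) for one gene, in label order."""
        row = self.expression.loc[gene, self.labels.index]
        mask = (self.labels == "tumor").to_numpy()
        vals = row.to_numpy(dtype=float)
        return vals[mask], vals[~mask]


@dataclass
class SurvivalCohort:
    """Per-patient follow-up, event status, gene expression and clinical covariates.

    ``time`` is overall survival in months; ``event`` is 1 for an observed
    death, 0 for censoring. ``expression`` is patients x genes (log2);
    ``covariates`` holds optional clinical variables aligned on patient id.
    """

    patient_id: Sequence[str]
    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.patient_id = list(self.patient_id)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != (len(self.patient_id),) or self.event.shape != self.time.shape:
            raise ValueError("patient_id, time and event must have equal length")
        if np.isnan(self.time).any() or np.isnan(self.event.astype(float)).any():
            raise ValueError("missing time or event values are not permitted; drop them at read time")
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")
        ev = self.event.astype(float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.event = ev.astype(int)
        for df_name in ("expression", "covariates"):
            df = getattr(self, df_name)
            if df is not None and list(df.index) != self.patient_id:
                setattr(self, df_name, df.loc[self.patient_id])

    @property
    def n_patients(self) -> int:
        return len(self.patient_id)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


class GeneAnnotation:
    """Gene -> cellular-component term-set mapping.

    A gene absent from the mapping is *unannotated* and distinguishable from
    a gene annotated with an empty (or non-matching) term set.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._terms = {g: frozenset(ts) for g, ts in mapping.items()}

    def __contains__(self, gene: str) -> bool:
        return gene in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def terms(self, gene: str) -> frozenset[str]:
        """Term set for an annotated gene; KeyError for an unannotated one."""
        return self._terms[gene]

    def matches(self, gene: str, target_terms: Iterable[str]) -> bool:
        """True iff the gene is annotated with at least one target term."""
        return gene in self._terms and bool(self._terms[gene] & set(target_terms))


# GO cellular-component term for the extracellular region, the default
# filter for blood-detectable candidates.
EXTRACELLULAR_REGION = "GO:0005576"


@dataclass
class AnalysisConfig:
    """Pipeline thresholds; the defaults reproduce the published settings.

    top_fraction
        Fraction of genes kept per cohort when ranking by positive rate.
    auc_threshold
        Diagnostic gate: a candidate survives only with AUC strictly above
        this value in every validation dataset.
    univariate_alpha / multivariate_alpha
        Significance levels of the two Cox selection stages.
    fc_threshold / adj_p_threshold
        Fold-change and BH-adjusted-p gates of the differential-expression
        baseline screen.
    """

    top_fraction: float = 0.05
    auc_threshold: float = 0.6
    univariate_alpha: float = 0.05
    multivariate_alpha: float = 0.05
    fc_threshold: float = 2.0
    adj_p_threshold: float = 0.05
    tie_policy: str = "not_positive"
    cox_tie_method: str = "breslow"
    random_seed: int = 0
    extracellular_terms: tuple[str, ...] = (EXTRACELLULAR_REGION,)

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if not 0 <= self.auc_threshold <= 1:
            raise ValueError("auc_threshold must lie in [0, 1]")
        for name in ("univariate_alpha", "multivariate_alpha", "adj_p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.tie_policy != "not_positive":
            raise ValueError("tie_policy: only 'not_positive' is defined")
        if self.cox_tie_method not in ("breslow", "efron"):
            raise ValueError("cox_tie_method must be 'breslow' or 'efron'")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        if "extracellular_terms" in data:
            data["extracellular_terms"] = tuple(data["extracellular_terms"])
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["extracellular_terms"] = list(self.extracellular_terms)
        return d
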