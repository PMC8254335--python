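"""Seeded generators for every input the pipeline consumes.

Three generators emulate the study conditions the analysis assumes:

* paired tumor/adjacent cohorts in which a planted subset of genes is
  over-expressed in nearly all pairs (the screening premise: a useful blood
  biomarker is elevated in almost every patient, not merely on average);
* survival cohorts whose hazards follow a proportional-hazards model on a
  linear predictor over signature genes, with independent uniform censoring
  calibrated to a target censoring fraction;
* two-group serum panels with published group means/SDs, marker-linked
  clinical categories and shrunk post-operative values.

Every generator is a pure function of its config (seed included): the same
config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import Pair, PairedExpressionCohort, SurvivalCohort
from .clinical import CLINICAL_LEVELS, DEFAULT_PANEL_WEIGHTS, MARKER_COLUMNS, SerumPanel

__all__ = [
    "ScreeningSimConfig",
    "SurvivalSimConfig",
    "SerumSimConfig",
    "simulate_paired_cohorts",
    "simulate_survival_cohort",
    "simulate_serum_panel",
]


@dataclass(frozen=True)
class ScreeningSimConfig:
    """Planted-marker paired-cohort simulation.

    The planted shift is parameterized on the scale the positive-rate
    statistic sees: with tumor - adjacent differences ~
    Normal(planted_shift, noise_sd), P(diff > 0) = planted_positive_prob
    fixes noise_sd = planted_shift / PhiInv(planted_positive_prob). The
    defaults plant a small (0.4 log2 units, ~1.3-fold) but near-universal
    (95% of pairs) shift — strong for a rate-based screen, invisible to a
    fold-change > 2 gate.
    """

    seed: int = 0
    n_genes: int = 2000
    n_pairs: int = 50
    n_cohorts: int = 3
    planted_gene_count: int = 30
    planted_positive_prob: float = 0.95
    background_positive_prob: float = 0.5
    planted_shift: float = 0.4
    noise_sd: float | None = None
    base_mean: float = 8.0
    base_sd: float = 1.5

    def __post_init__(self) -> None:
        for p in (self.planted_positive_prob, self.background_positive_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_gene_count > self.n_genes:
            raise ValueError("planted_gene_count exceeds n_genes")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        if self.planted_positive_prob >= 1.0 or self.planted_positive_prob <= 0.5:
            raise ValueError(
                "noise_sd cannot be derived for planted_positive_prob outside (0.5, 1); set it explicitly"
            )
        return self.planted_shift / stats.norm.ppf(self.planted_positive_prob)


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Proportional-hazards survival simulation.

    Event times are exponential with rate lambda0 * exp(beta' x) over
    standard-normal gene expression; the default coefficients are the
    published three-gene risk-model values. ``censoring_fraction`` is hit
    by calibrating the scale of an independent uniform censoring time.
    ``n_noise_genes`` appends pure-noise genes (true beta = 0), giving the
    signature builder a candidate pool with known truth.
    """

    seed: int = 0
    n_patients: int = 600
    signature_genes: tuple[str, ...] = ("AGT", "SERPINH1", "MMP7")
    true_betas: tuple[float, ...] = (0.180, 0.544, 0.135)
    baseline_hazard: float = 0.02  # events per month
    censoring_fraction: float = 0.3
    n_noise_genes: int = 0
    clinical_covariates: bool = False
    clinical_assoc: float = 1.0  # log-odds of adverse stage per unit linear predictor

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if len(self.signature_genes) != len(self.true_betas):
            raise ValueError("signature_genes and true_betas must have equal length")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


# Published serum concentration moments (mean, SD) per marker and group.
_GC_MOMENTS = {"agt_ng_ml": (34.51, 22.35), "serpinh1_pg_ml": (733.90, 204.65), "mmp7_ng_ml": (4.67, 1.30)}
_CONTROL_MOMENTS = {"agt_ng_ml": (25.90, 16.08), "serpinh1_pg_ml": (604.41, 185.04), "mmp7_ng_ml": (3.80, 2.27)}

# Baseline probability of each clinical variable's adverse level (levels
# themselves live in clinical.CLINICAL_LEVELS).
_CLINICAL_BASE_P = {
    "tumor_size": 0.42,
    "tumor_invasion": 0.69,
    "lymph_node_invasion": 0.63,
    "metastasis": 0.16,
    "stage": 0.53,
    "gender": 0.68,
    "age_group": 0.40,
}


@dataclass(frozen=True)
class SerumSimConfig:
    """Two-group serum panel simulation.

    Concentrations are truncated-at-zero Normal by default (the published
    summaries are means and SDs; truncation adds positivity with no further
    assumptions), log-Normal matched to the same moments by flag. Adverse
    clinical categories are linked to marker level through a configurable
    odds ratio; post-operative concentrations are pre-operative values
    shrunk by a common factor plus noise.
    """

    seed: int = 0
    n_gc: int = 132
    n_control: int = 86
    gc_moments: dict = field(default_factory=lambda: dict(_GC_MOMENTS))
    control_moments: dict = field(default_factory=lambda: dict(_CONTROL_MOMENTS))
    distribution: str = "truncnorm"  # or "lognormal"
    clinical_odds_ratio: float = 3.0
    n_postop: int = 25
    postop_shrinkage: float = 0.75
    postop_noise_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.n_gc < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        if self.distribution not in ("truncnorm", "lognormal"):
            raise ValueError("distribution must be 'truncnorm' or 'lognormal'")
        for moments in (self.gc_moments, self.control_moments):
            for m, s in moments.values():
                if s <= 0:
                    raise ValueError("serum SDs must be positive")
        if not 0 <= self.n_postop <= self.n_gc:
            raise ValueError("n_postop must lie in [0, n_gc]")


def simulate_paired_cohorts(config: ScreeningSimConfig) -> tuple[list[PairedExpressionCohort], list[str]]:
    """Generate paired cohorts with a shared planted marker set.

    Returns (cohorts, planted gene ids). Background genes have
    P(tumor > adjacent) = background_positive_prob per pair; planted genes
    P = planted_positive_prob (exactly 1 when configured so, via a
    reflected normal difference). The planted set is identical across
    cohorts.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    planted_idx = rng.choice(config.n_genes, size=config.planted_gene_count, replace=False)
    planted_idx.sort()
    planted = [genes[i] for i in planted_idx]

    exact = config.planted_positive_prob >= 1.0
    sd = config.noise_sd if (exact and config.noise_sd is not None) else None
    if sd is None:
        sd = 0.25 if exact else config.resolved_noise_sd()
    bg_shift = sd * stats.norm.ppf(config.background_positive_prob) if config.background_positive_prob not in (0.0, 1.0) else 0.0

    cohorts = []
    for c in range(config.n_cohorts):
        adjacent = rng.normal(config.base_mean, config.base_sd, size=(config.n_genes, config.n_pairs))
        diffs = rng.normal(bg_shift, sd, size=(config.n_genes, config.n_pairs))
        planted_diffs = rng.normal(config.planted_shift, sd, size=(config.planted_gene_count, config.n_pairs))
        if exact:
            planted_diffs = np.abs(planted_diffs)
        diffs[planted_idx] = planted_diffs
        tumor = adjacent + diffs
        pairs, columns, data = [], [], []
        for j in range(config.n_pairs):
            sid = f"subj_{c}_{j:03d}"
            pairs.append(Pair(sid, f"{sid}_T", f"{sid}_A"))
            columns += [f"{sid}_T", f"{sid}_A"]
            data += [tumor[:, j], adjacent[:, j]]
        expr = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=columns)
        cohorts.append(PairedExpressionCohort(f"sim_cohort_{c}", expr, pairs))
    return cohorts, planted


def _calibrate_uniform_censoring(latent_times: np.ndarray, target: float) -> float:
    """Scale c of C ~ U(0, c) such that the expected censored fraction,
    mean_i P(C_i < T_i) = mean_i min(T_i / c, 1), equals ``target``."""
    lo, hi = 1e-9, float(latent_times.max()) * 1e4

    def frac(c):
        return float(np.minimum(latent_times / c, 1.0).mean())

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival_cohort(config: SurvivalSimConfig) -> tuple[SurvivalCohort, dict]:
    """Generate a proportional-hazards survival cohort.

    Returns (cohort, truth) where truth records the true coefficients, the
    baseline hazard, the censoring scale and the noise-gene ids.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sig_genes = list(config.signature_genes)
    noise_genes = [f"noise_{i:03d}" for i in range(config.n_noise_genes)]
    genes = sig_genes + noise_genes
    X = rng.normal(size=(n, len(genes)))
    beta = np.concatenate([np.asarray(config.true_betas, dtype=float), np.zeros(config.n_noise_genes)])
    lp = X @ beta
    rate = config.baseline_hazard * np.exp(lp)
    latent = rng.exponential(1.0 / rate)
    if config.censoring_fraction > 0:
        c_scale = _calibrate_uniform_censoring(latent, config.censoring_fraction)
        censor = rng.uniform(0.0, c_scale, size=n)
        time = np.minimum(latent, censor)
        event = (latent <= censor).astype(int)
    else:
        c_scale = np.inf
        time, event = latent, np.ones(n, dtype=int)

    patients = [f"patient_{i:04d}" for i in range(n)]
    expr = pd.DataFrame(X, index=pd.Index(patients), columns=genes)
    covariates = None
    if config.clinical_covariates:
        z = (lp - lp.mean()) / (lp.std() or 1.0)
        p_stage = 1.0 / (1.0 + np.exp(-(config.clinical_assoc * z)))
        stage = np.where(rng.random(n) < p_stage, "III-IV", "I-II")
        covariates = pd.DataFrame(
            {
                "gender": rng.choice(["male", "female"], size=n),
                "age_group": rng.choice(["<=65", ">65"], size=n, p=[0.6, 0.4]),
                "stage": stage,
            },
            index=pd.Index(patients),
        )
    cohort = SurvivalCohort(patients, time, event, expression=expr, covariates=covariates)
    truth = {
        "genes": genes,
        "beta": beta,
        "baseline_hazard": config.baseline_hazard,
        "censoring_scale": c_scale,
        "noise_genes": noise_genes,
    }
    return cohort, truth


def _draw_concentrations(rng, moments: dict, n: int, distribution: str) -> pd.DataFrame:
    cols = {}
    for marker in MARKER_COLUMNS:
        mean, sd = moments[marker]
        if distribution == "truncnorm":
            a = (0.0 - mean) / sd
            tn = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
            cols[marker] = tn.ppf(rng.random(n))
        else:
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            cols[marker] = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))
    return pd.DataFrame(cols)


def simulate_serum_panel(config: SerumSimConfig) -> SerumPanel:
    """Generate a two-group serum panel with clinical and post-operative data.

    GC subjects get clinical categories whose adverse-level odds are
    multiplied by ``clinical_odds_ratio`` when the subject's weighted panel
    score is above its median; the first ``n_postop`` GC subjects get
    paired post-operative concentrations.
    """
    rng = np.random.default_rng(config.seed)
    gc = _draw_concentrations(rng, config.gc_moments, config.n_gc, config.distribution)
    ctrl = _draw_concentrations(rng, config.control_moments, config.n_control, config.distribution)
    gc["group"] = "GC"
    ctrl["group"] = "control"

    # link clinical categories to marker burden via the weighted panel score
    score = gc[list(MARKER_COLUMNS)].to_numpy() @ np.asarray(DEFAULT_PANEL_WEIGHTS)
    high = score > np.median(score)
    for var, base_p in _CLINICAL_BASE_P.items():
        reference, adverse = CLINICAL_LEVELS[var]
        odds = base_p / (1 - base_p)
        linked = var not in ("gender", "age_group")
        odds_vec = np.where(high & linked, odds * config.clinical_odds_ratio, odds)
        p = odds_vec / (1 + odds_vec)
        gc[var] = np.where(rng.random(config.n_gc) < p, adverse, reference)

    for marker in MARKER_COLUMNS:
        post = np.full(config.n_gc, np.nan)
        if config.n_postop:
            pre = gc[marker].to_numpy()[: config.n_postop]
            noise = rng.normal(1.0, config.postop_noise_cv, size=config.n_postop)
            post[: config.n_postop] = np.maximum(pre * config.postop_shrinkage * noise, 1e-6)
        gc[f"post_{marker}"] = post

    data = pd.concat([gc, ctrl], ignore_index=True)
    data.insert(0, "subject_id", [f"subj_{i:04d}" for i in range(len(data))])
    return SerumPanel(data)
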