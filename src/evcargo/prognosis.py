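"""Clinical-association workflow for hub-gene expression.

Per gene: unbiased two-class patient stratification by a univariate
two-component Gaussian mixture (median-split fallback), Shapiro-Wilk-gated
parametric/nonparametric comparison against clinical categories,
single-feature ROC AUC with a 70% decision threshold, and median-split
Kaplan-Meier survival with the log-rank test. All p-values are unadjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.mixture import GaussianMixture

from evcargo.datatypes import ClinicalCohort

log = logging.getLogger(__name__)

AUC_THRESHOLD = 0.70


# ------------------------------------------------------------ GMM split

@dataclass
class GmmSplit:
    gene: str
    assignment: pd.Series             # patient -> "low" | "high"
    component_means: tuple[float, float]
    method: str                       # "gmm2" | "median_fallback"

    @property
    def low_patients(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "low"])

    @property
    def high_patients(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "high"])


def gmm_split(cohort: ClinicalCohort, gene: str, random_state: int = 0) -> GmmSplit:
    """Two-class patient stratification by expression of ``gene``.

    Fits univariate 2-component Gaussian mixtures by EM (equal-variance and
    free-variance, best by BIC) against a 1-component model. If the
    1-component model wins, or a class would be empty, falls back to a
    median split (ties to low) and records the method.
    """
    x = cohort.expression[gene].dropna()
    if len(x) < 10:
        raise ValueError(f"need >= 10 patients with expression for {gene!r}, have {len(x)}")
    if x.nunique() == 1:
        raise ValueError(f"constant expression for {gene!r}")
    arr = x.to_numpy(dtype=float).reshape(-1, 1)

    candidates = []
    for cov in ("tied", "full"):
        gm = GaussianMixture(n_components=2, covariance_type=cov,
                             n_init=5, random_state=random_state)
        gm.fit(arr)
        candidates.append((gm.bic(arr), cov, gm))
    gm1 = GaussianMixture(n_components=1, covariance_type="full",
                          random_state=random_state).fit(arr)
    bic1 = gm1.bic(arr)
    best_bic, _, best = min(candidates, key=lambda c: c[0])

    if best_bic < bic1:
        labels = best.predict(arr)
        means = best.means_.ravel()
        low_comp = int(np.argmin(means))
        assignment = pd.Series(
            np.where(labels == low_comp, "low", "high"), index=x.index
        )
        if (assignment == "low").any() and (assignment == "high").any():
            return GmmSplit(
                gene=gene,
                assignment=assignment,
                component_means=(float(means.min()), float(means.max())),
                method="gmm2",
            )
    # median fallback (1-component preferred or a class came out empty)
    cut = float(x.median())
    assignment = pd.Series(np.where(x <= cut, "low", "high"), index=x.index)
    low_mean = float(x[assignment == "low"].mean())
    high_mean = float(x[assignment == "high"].mean()) if (assignment == "high").any() else low_mean
    return GmmSplit(gene=gene, assignment=assignment,
                    component_means=(low_mean, high_mean), method="median_fallback")


# ------------------------------------------- category association tests

@dataclass
class AssociationResult:
    gene: str
    category: str
    test_used: str                    # student_t | anova | wilcoxon | kruskal_wallis
    p_value: float
    normality_p: dict[str, float] = field(default_factory=dict)
    levene_p: float = float("nan")
    n_per_level: dict[str, int] = field(default_factory=dict)


def associate_with_category(
    cohort: ClinicalCohort, gene: str, category: str
) -> AssociationResult:
    """Compare ``gene`` expression across the levels of a clinical category.

    Shapiro-Wilk on each level gates the test: all levels normal
    (p > 0.05) gives Student t (2 levels) or one-way ANOVA (>2); otherwise
    Wilcoxon rank-sum (2) or Kruskal-Wallis (>2). A level with n < 3
    forces the nonparametric branch (Shapiro-Wilk undefined there).
    Homogeneity of variance (Levene) is recorded but not gating.
    """
    expr = cohort.expression[gene]
    levels = cohort.categories[category].dropna()
    groups: dict[str, np.ndarray] = {}
    for level in sorted(levels.unique()):
        vals = expr[levels.index[levels == level]].dropna().to_numpy(dtype=float)
        if len(vals):
            groups[level] = vals
    if len(groups) < 2:
        raise ValueError(f"category {category!r} needs >= 2 non-empty levels")

    small = [lvl for lvl, v in groups.items() if len(v) < 3]
    normality_p: dict[str, float] = {}
    if small:
        log.info("category %s: level(s) %s have n < 3; forcing nonparametric test",
                 category, small)
        normal = False
    else:
        for lvl, v in groups.items():
            normality_p[lvl] = float(stats.shapiro(v).pvalue) if np.ptp(v) > 0 else 0.0
        normal = all(p > 0.05 for p in normality_p.values())

    levene_p = float("nan")
    if not small and all(len(v) >= 2 for v in groups.values()):
        levene_p = float(stats.levene(*groups.values()).pvalue)

    vals = list(groups.values())
    if normal:
        if len(vals) == 2:
            test_used = "student_t"
            p = float(stats.ttest_ind(vals[0], vals[1], equal_var=True).pvalue)
        else:
            test_used = "anova"
            p = float(stats.f_oneway(*vals).pvalue)
    else:
        if len(vals) == 2:
            test_used = "wilcoxon"
            p = float(stats.ranksums(vals[0], vals[1]).pvalue)
        else:
            test_used = "kruskal_wallis"
            p = float(stats.kruskal(*vals).pvalue)
    return AssociationResult(
        gene=gene, category=category, test_used=test_used, p_value=p,
        normality_p=normality_p, levene_p=levene_p,
        n_per_level={lvl: len(v) for lvl, v in groups.items()},
    )


# ------------------------------------------------------------- ROC AUC

@dataclass
class RocResult:
    gene: str
    dichotomy: str
    auc: float                        # P(score_pos > score_neg) + 1/2 P(tie)
    discrimination: float             # max(auc, 1 - auc)
    passes_threshold: bool            # auc >= 0.70
    n_positive: int
    n_negative: int


def roc_auc(
    cohort: ClinicalCohort,
    gene: str,
    labels: pd.Series,
    dichotomy: str = "",
) -> RocResult:
    """Single-feature ROC AUC of ``gene`` expression for a binary outcome.

    ``labels`` is a boolean per-patient series (True = positive class).
    AUC is the Mann-Whitney statistic U/(n1*n2) with midrank tie handling;
    the orientation is as given (higher expression scoring the positive
    class), with ``discrimination`` = max(auc, 1-auc) reported alongside.
    """
    expr = cohort.expression[gene]
    common = labels.dropna().index.intersection(expr.dropna().index)
    y = labels.loc[common].astype(bool)
    x = expr.loc[common].to_numpy(dtype=float)
    pos, neg = x[y.to_numpy()], x[~y.to_numpy()]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty for ROC")
    u = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic)
    auc = u / (len(pos) * len(neg))
    return RocResult(
        gene=gene, dichotomy=dichotomy, auc=auc,
        discrimination=max(auc, 1.0 - auc),
        passes_threshold=auc >= AUC_THRESHOLD,
        n_positive=int(len(pos)), n_negative=int(len(neg)),
    )


# --------------------------------------------- Kaplan-Meier + log-rank

@dataclass
class SurvivalResult:
    gene: str
    cut: float                        # median expression
    curves: pd.DataFrame              # time, arm, survival, at_risk
    chi_square: float
    p_value: float
    n_low: int
    n_high: int


def km_logrank(cohort: ClinicalCohort, gene: str) -> SurvivalResult:
    """Median-split Kaplan-Meier comparison tested by the log-rank statistic.

    Patients at or below the median expression form the low arm (ties to
    low, configurable nowhere on purpose: the convention is part of the
    contract). Product-limit curves per arm; two-sample log-rank
    chi-square with 1 df.
    """
    expr = cohort.expression[gene].dropna()
    idx = expr.index
    if int(cohort.event.loc[idx].sum()) < 2:
        raise ValueError("need >= 2 observed events for the log-rank test")
    cut = float(expr.median())
    low = expr.index[expr <= cut]
    high = expr.index[expr > cut]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("median split produced an empty arm")

    curves = []
    for arm, members in (("low", low), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.survival_time.loc[members], cohort.event.loc[members], label=arm)
        surv = kmf.survival_function_[arm]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves.append(pd.DataFrame({
            "time": surv.index, "arm": arm,
            "survival": surv.to_numpy(), "at_risk": at_risk.to_numpy(),
        }))
    res = logrank_test(
        cohort.survival_time.loc[low], cohort.survival_time.loc[high],
        event_observed_A=cohort.event.loc[low], event_observed_B=cohort.event.loc[high],
    )
    return SurvivalResult(
        gene=gene, cut=cut, curves=pd.concat(curves, ignore_index=True),
        chi_square=float(res.test_statistic), p_value=float(res.p_value),
        n_low=int(len(low)), n_high=int(len(high)),
    )


# ------------------------------------------------------- full workflow

def screen_prognostic(
    cohort: ClinicalCohort,
    genes: list[str] | None = None,
    category: str | None = None,
    auc_threshold: float = AUC_THRESHOLD,
) -> pd.DataFrame:
    """Run the full per-gene workflow over the cohort.

    For each gene: category association p (against ``category``, or the
    first available one), AUC for the same dichotomy (first level sorted =
    negative class for >2-level categories the first two levels are used),
    and median-split log-rank p. ``passes`` requires association p <= 0.05,
    AUC >= threshold, and log-rank p <= 0.05 simultaneously.
    """
    if genes is None:
        genes = cohort.genes
    if category is None:
        if cohort.categories.shape[1] == 0:
            raise ValueError("cohort has no clinical categories")
        category = cohort.categories.columns[0]
    levels = sorted(cohort.categories[category].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"category {category!r} needs >= 2 levels")
    pos_level = levels[1]
    labels = cohort.categories[category].map(lambda v: v == pos_level if pd.notna(v) else np.nan)

    rows = []
    for gene in genes:
        assoc = associate_with_category(cohort, gene, category)
        roc = roc_auc(cohort, gene, labels, dichotomy=f"{category}:{pos_level}")
        surv = km_logrank(cohort, gene)
        rows.append({
            "gene": gene,
            "category": category,
            "association_test": assoc.test_used,
            "association_p": assoc.p_value,
            "auc": roc.auc,
            "discrimination": roc.discrimination,
            "logrank_chi2": surv.chi_square,
            "logrank_p": surv.p_value,
            "passes": (assoc.p_value <= 0.05
                       and roc.auc >= auc_threshold
                       and surv.p_value <= 0.05),
        })
    return pd.DataFrame(rows)
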