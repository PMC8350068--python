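import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evcargo import prognosis as pr
from evcargo import simulate as sim
from evcargo.datatypes import ClinicalCohort
from conftest import small_spec


def make_cohort(expr: dict, time=None, event=None, categories: dict | None = None):
    n = len(next(iter(expr.values())))
    pids = [f"P{i + 1:03d}" for i in range(n)]
    rng = np.random.default_rng(0)
    if time is None:
        time = rng.exponential(10, size=n)
    if event is None:
        event = np.ones(n, dtype=bool)
    cats = pd.DataFrame(categories or {}, index=pids)
    return ClinicalCohort(
        expression=pd.DataFrame({g: np.asarray(v, float) for g, v in expr.items()},
                                index=pids),
        categories=cats,
        survival_time=pd.Series(np.asarray(time, float), index=pids),
        event=pd.Series(np.asarray(event, bool), index=pids),
    )


def logrank_chi2_oracle(time1, event1, time2, event2):
    """Hand-computed observed-minus-expected log-rank chi-square (1 df)."""
    times = sorted({t for t, e in zip(list(time1) + list(time2),
                                      list(event1) + list(event2)) if e})
    O1 = E1 = V = 0.0
    for t in times:
        n1 = sum(1 for x in time1 if x >= t)
        n2 = sum(1 for x in time2 if x >= t)
        d1 = sum(1 for x, e in zip(time1, event1) if x == t and e)
        d2 = sum(1 for x, e in zip(time2, event2) if x == t and e)
        n, d = n1 + n2, d1 + d2
        if n < 1:
            continue
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestGmmSplit:
    def test_well_separated_mixture_assignment_accuracy(self):
        rng = np.random.default_rng(1)
        truth = rng.random(100) < 0.5
        x = np.where(truth, rng.normal(10, 1, 100), rng.normal(0, 1, 100))
        cohort = make_cohort({"G": x})
        split = pr.gmm_split(cohort, "G")
        assert split.method == "gmm2"
        predicted_high = (split.assignment == "high").to_numpy()
        acc = max((predicted_high == truth).mean(), (predicted_high == ~truth).mean())
        assert acc >= 0.99

    def test_two_point_data_splits_by_sign(self):
        x = np.array([-1.0] * 10 + [1.0] * 10)
        cohort = make_cohort({"G": x})
        split = pr.gmm_split(cohort, "G")
        assert (split.assignment.iloc[:10] == "low").all()
        assert (split.assignment.iloc[10:] == "high").all()

    def test_unimodal_data_falls_back_to_median(self):
        rng = np.random.default_rng(2)
        cohort = make_cohort({"G": rng.normal(0, 1, 101)})
        split = pr.gmm_split(cohort, "G")
        assert split.method == "median_fallback"
        n_low = (split.assignment == "low").sum()
        n_high = (split.assignment == "high").sum()
        assert {n_low, n_high} == {50, 51}

    def test_constant_expression_hard_error(self):
        cohort = make_cohort({"G": np.full(20, 3.0)})
        with pytest.raises(ValueError, match="constant"):
            pr.gmm_split(cohort, "G")

    def test_low_class_mean_below_high(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(6, 1, 50)])
        split = pr.gmm_split(make_cohort({"G": x}), "G")
        assert split.component_means[0] < split.component_means[1]


class TestCategoryAssociation:
    def test_normal_branch_matches_closed_form_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        cohort = make_cohort({"G": np.concatenate([a, b])},
                             categories={"grp": ["lo"] * 30 + ["hi"] * 30})
        res = pr.associate_with_category(cohort, "G", "grp")
        assert res.test_used == "student_t"
        # independent pooled-t oracle
        sp2 = (a.var(ddof=1) * 29 + b.var(ddof=1) * 29) / 58
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 30))
        p = 2 * stats.t.sf(abs(t), 58)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_heavy_tailed_data_routes_nonparametric(self):
        rng = np.random.default_rng(5)
        a = rng.standard_cauchy(40)
        b = rng.standard_cauchy(40) + 1
        cohort = make_cohort({"G": np.concatenate([a, b])},
                             categories={"grp": ["lo"] * 40 + ["hi"] * 40})
        res = pr.associate_with_category(cohort, "G", "grp")
        assert res.test_used == "wilcoxon"

    def test_three_levels_use_anova_or_kruskal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 90)
        cohort = make_cohort({"G": x},
                             categories={"grp": ["a"] * 30 + ["b"] * 30 + ["c"] * 30})
        res = pr.associate_with_category(cohort, "G", "grp")
        assert res.test_used in ("anova", "kruskal_wallis")
        if res.test_used == "anova":
            assert all(p > 0.05 for p in res.normality_p.values())

    def test_tiny_level_forces_nonparametric(self):
        rng = np.random.default_rng(7)
        cohort = make_cohort({"G": rng.normal(0, 1, 22)},
                             categories={"grp": ["a"] * 20 + ["b"] * 2})
        res = pr.associate_with_category(cohort, "G", "grp")
        assert res.test_used == "wilcoxon"

    def test_single_level_category_rejected(self):
        cohort = make_cohort({"G": np.arange(10.0)}, categories={"grp": ["a"] * 10})
        with pytest.raises(ValueError, match="2 non-empty levels"):
            pr.associate_with_category(cohort, "G", "grp")

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(0, 1, 40)
            cohort = make_cohort({"G": x}, categories={"grp": ["a"] * 20 + ["b"] * 20})
            if pr.associate_with_category(cohort, "G", "grp").p_value <= 0.05:
                hits += 1
        assert abs(hits / n_sim - 0.05) <= 0.04


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        cohort = make_cohort({"G": np.concatenate([np.zeros(10), np.ones(10) + 5])})
        labels = pd.Series([False] * 10 + [True] * 10, index=cohort.patient_ids)
        res = pr.roc_auc(cohort, "G", labels)
        assert res.auc == 1.0 and res.passes_threshold

    def test_ties_heavy_example_matches_all_pairs_oracle(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([False, True, False, True, True, False, True, True])
        cohort = make_cohort({"G": x})
        labels = pd.Series(y, index=cohort.patient_ids)
        res = pr.roc_auc(cohort, "G", labels)
        pos, neg = x[y], x[~y]
        pairs = [(p, q) for p in pos for q in neg]
        oracle = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p, q in pairs) / len(pairs)
        assert res.auc == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 50)
        y = rng.random(50) < 0.4
        c1 = make_cohort({"G": x})
        c2 = make_cohort({"G": np.exp(x)})
        labels = pd.Series(y, index=c1.patient_ids)
        assert (pr.roc_auc(c1, "G", labels).auc
                == pytest.approx(pr.roc_auc(c2, "G", labels).auc, rel=1e-12))

    def test_seventy_percent_threshold_behavior(self):
        # a marker simulated to discriminate at AUC ~ 0.736 should pass
        rng = np.random.default_rng(10)
        n = 4000
        y = rng.random(n) < 0.5
        # normal shift model: AUC = Phi(delta/sqrt(2)); delta for AUC 0.736
        delta = np.sqrt(2) * stats.norm.ppf(0.736)
        x = rng.normal(0, 1, n) + y * delta
        cohort = make_cohort({"G": x})
        res = pr.roc_auc(cohort, "G", pd.Series(y, index=cohort.patient_ids))
        assert res.auc == pytest.approx(0.736, abs=0.03)
        assert res.passes_threshold

    def test_empty_class_hard_error(self):
        cohort = make_cohort({"G": np.arange(5.0)})
        labels = pd.Series([True] * 5, index=cohort.patient_ids)
        with pytest.raises(ValueError, match="non-empty"):
            pr.roc_auc(cohort, "G", labels)


class TestKmLogrank:
    def test_identical_arms_chi2_zero_p_one(self):
        time = [1.0, 2, 3, 4, 1, 2, 3, 4]
        event = [True] * 8
        expr = [0.0, 0, 0, 0, 1, 1, 1, 1]  # median split puts duplicates apart
        cohort = make_cohort({"G": expr}, time=time, event=event)
        res = pr.km_logrank(cohort, "G")
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_six_patient_hand_table_matches_oracle(self):
        time = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        event = [True, True, False, True, True, True]
        expr = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
        cohort = make_cohort({"G": expr}, time=time, event=event)
        res = pr.km_logrank(cohort, "G")
        expected = logrank_chi2_oracle(time[:3], event[:3], time[3:], event[3:])
        assert res.chi_square == pytest.approx(expected, rel=1e-6)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-6)

    def test_p_invariant_to_arm_label_swap(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 40)
        time = rng.exponential(10, 40)
        cohort1 = make_cohort({"G": x}, time=time)
        cohort2 = make_cohort({"G": -x}, time=time)
        r1, r2 = pr.km_logrank(cohort1, "G"), pr.km_logrank(cohort2, "G")
        # -x swaps which patients sit in the low arm (up to median-tie edge cases)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)

    def test_curves_start_at_one_and_never_increase(self, study):
        gene = next(iter(study.truth.prognostic_genes))
        res = pr.km_logrank(study.cohort, gene)
        for arm in ("low", "high"):
            surv = res.curves[res.curves["arm"] == arm]["survival"].to_numpy()
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()

    def test_arms_partition_patients(self, study):
        gene = study.cohort.genes[0]
        res = pr.km_logrank(study.cohort, gene)
        assert res.n_low + res.n_high == len(study.cohort.patient_ids)

    def test_planted_hazard_gene_detected(self, study):
        gene = next(iter(study.truth.prognostic_genes))
        assert pr.km_logrank(study.cohort, gene).p_value <= 0.05


class TestWorkflow:
    def test_null_cohort_rarely_passes_joint_criterion(self):
        spec = small_spec(seed=31)
        spec.cohort = sim.CohortSpec(n_patients=100, n_prognostic_genes=0,
                                     n_null_genes=40, hazard_ratio=1.0)
        study = sim.generate_study(spec)
        screen = pr.screen_prognostic(study.cohort)
        assert screen["passes"].mean() <= 0.05

    def test_planted_gene_flagged_by_full_workflow(self, study):
        screen = pr.screen_prognostic(study.cohort)
        flagged = set(screen[screen["passes"]]["gene"])
        assert study.truth.category_genes[0] in flagged
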