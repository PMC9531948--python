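"""KM, log-rank, AUC, NRI, IDI, DCA against hand and enumeration oracles."""

import numpy as np
import pytest

import graphsurv as gs
from graphsurv.evaluation import EvaluationError, horizon_labels


def km_oracle(times, events):
    """Closed-form product over distinct event times."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for ut in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= ut)
        d = np.sum((times == ut) & (events == 1))
        s *= 1.0 - d / n_at_risk
        out_t.append(ut)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        c = gs.km_curve([3.0, 8.0, 12.0], [0, 0, 0])
        assert c.event_times.size == 0 or np.all(c.survival == 1.0)

    def test_hand_product_limit(self):
        c = gs.km_curve([5.0, 10.0, 15.0], [1, 1, 0])
        np.testing.assert_allclose(c.event_times, [5.0, 10.0])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3])
        np.testing.assert_allclose(c.at_risk, [3, 2])

    def test_exhaustion_reaches_zero(self):
        c = gs.km_curve([2.0, 4.0], [1, 1])
        assert c.survival[-1] == pytest.approx(0.0)

    def test_matches_closed_form_on_random_fixtures(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            t = rng.choice([1.0, 2.0, 3.0, 5.0, 8.0, 13.0], n)
            e = rng.integers(0, 2, n)
            c = gs.km_curve(t, e)
            ot, os_ = km_oracle(t, e)
            np.testing.assert_allclose(c.event_times, ot)
            np.testing.assert_allclose(c.survival, os_, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(EvaluationError):
            gs.km_curve([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        stat, p = gs.logrank([1, 2, 3], [1, 0, 1], [1, 2, 3], [1, 0, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(30, 10), rng.exponential(60, 12)
        ea, eb = rng.integers(0, 2, 10), rng.integers(0, 2, 12)
        ea[0] = eb[0] = 1
        s1, _ = gs.logrank(ta, ea, tb, eb)
        s2, _ = gs.logrank(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_eight_patient_observed_minus_expected(self):
        # group A: times 1,3,5,7 events 1,1,0,1; group B: 2,4,6,8 events 1,0,1,0
        ta, ea = [1.0, 3.0, 5.0, 7.0], [1, 1, 0, 1]
        tb, eb = [2.0, 4.0, 6.0, 8.0], [1, 0, 1, 0]
        t = np.array(ta + tb)
        e = np.array(ea + eb)
        grp = np.array([0] * 4 + [1] * 4)
        O_E, V = 0.0, 0.0
        for ut in np.unique(t[e == 1]):
            at = t >= ut
            n, n1 = at.sum(), (at & (grp == 0)).sum()
            d = ((t == ut) & (e == 1)).sum()
            d1 = ((t == ut) & (e == 1) & (grp == 0)).sum()
            O_E += d1 - d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        stat, _ = gs.logrank(ta, ea, tb, eb)
        assert stat == pytest.approx(O_E ** 2 / V, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(EvaluationError):
            gs.logrank([], [], [1.0], [1])


class TestRiskStratify:
    def test_clear_split(self):
        groups = gs.risk_stratify([1, 2, 3, 4, 0, 5], [True] * 4 + [False] * 2)
        assert list(groups.labels[4:]) == ["low", "high"]

    def test_all_equal_risks_labelled_low(self):
        groups = gs.risk_stratify([2.0] * 5, [True] * 5)
        assert set(groups.labels) == {"low"}

    def test_threshold_from_training_nodes_only(self, rng):
        risks = rng.normal(size=30)
        mask = np.zeros(30, bool)
        mask[:20] = True
        t1 = gs.risk_stratify(risks, mask).threshold
        risks2 = risks.copy()
        risks2[25] += 100.0  # test node
        t2 = gs.risk_stratify(risks2, mask).threshold
        assert t1 == t2


class TestAuc:
    def test_perfect_ranking(self):
        auc, _ = gs.auc_ci([4, 3, 2, 1], [10, 20, 70, 80], [1, 1, 0, 0],
                           horizon=60, n_boot=20, seed=0)
        assert auc == 1.0

    def test_uninformative_score(self):
        auc, _ = gs.auc_ci([1.0] * 6, [10, 20, 30, 70, 80, 90], [1, 1, 1, 0, 0, 0],
                           horizon=60, n_boot=20, seed=0)
        assert auc == pytest.approx(0.5)

    def test_pairwise_concordance_oracle(self, rng):
        risks = rng.normal(size=10)
        times = rng.uniform(1, 120, 10)
        events = rng.integers(0, 2, 10)
        events[times.argmin()] = 1
        labels, keep = horizon_labels(times, events, 60.0)
        r = risks[keep]
        pos, neg = r[labels == 1], r[labels == 0]
        if pos.size and neg.size:
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            auc, _ = gs.auc_ci(risks, times, events, 60.0, n_boot=10, seed=0)
            assert auc == pytest.approx(conc / (pos.size * neg.size))

    def test_monotone_transform_invariance(self, rng):
        risks = rng.normal(size=40)
        times = rng.uniform(1, 120, 40)
        events = rng.integers(0, 2, 40)
        events[:5] = 1
        times[:5] = 10.0
        a1, _ = gs.auc_ci(risks, times, events, n_boot=10, seed=0)
        a2, _ = gs.auc_ci(np.exp(3 * risks), times, events, n_boot=10, seed=0)
        assert a1 == pytest.approx(a2)

    def test_censored_before_horizon_excluded(self):
        # subject censored at 30 months carries no 60-month label
        labels, keep = horizon_labels([30.0, 70.0, 20.0], [0, 0, 1], 60.0)
        np.testing.assert_array_equal(keep, [False, True, True])
        np.testing.assert_array_equal(labels, [0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            gs.auc_ci([1, 2], [70, 80], [0, 0], horizon=60, n_boot=10, seed=0)


class TestNri:
    def test_identity_is_zero(self, rng):
        r = rng.normal(size=12)
        labels = np.array([1] * 6 + [0] * 6)
        assert gs.nri(r, r, labels, n_boot=20)[0] == 0.0

    def test_maximal_improvement_is_two(self):
        old = np.array([0.5] * 8)
        new = np.array([1.0] * 4 + [0.0] * 4)
        labels = np.array([1] * 4 + [0] * 4)
        assert gs.nri(old, new, labels, n_boot=20)[0] == 2.0

    def test_eight_subject_counting_oracle(self):
        old = np.array([0.1, 0.4, 0.5, 0.7, 0.2, 0.3, 0.6, 0.8])
        new = np.array([0.3, 0.3, 0.9, 0.7, 0.1, 0.5, 0.2, 0.6])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        # events: up 2 (0,2), down 1 (1), tie 1 -> (2-1)/4 = 0.25
        # non-events: down 3 (4,6,7), up 1 (5) -> (3-1)/4 = 0.5
        assert gs.nri(old, new, labels, n_boot=20)[0] == pytest.approx(0.75)

    def test_antisymmetry(self, rng):
        old, new = rng.normal(size=16), rng.normal(size=16)
        labels = rng.integers(0, 2, 16)
        labels[0], labels[1] = 0, 1
        assert gs.nri(old, new, labels, n_boot=10)[0] == pytest.approx(
            -gs.nri(new, old, labels, n_boot=10)[0])

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            gs.nri([1, 2], [2, 1], [1, 1])


class TestIdi:
    def test_identity_is_zero(self, rng):
        r = rng.uniform(size=10)
        labels = np.array([1] * 5 + [0] * 5)
        assert gs.idi(r, r, labels, n_boot=10)[0] == 0.0

    def test_perfect_new_model_closed_form(self):
        old = np.array([0.5] * 8)
        new = np.array([1.0] * 4 + [0.0] * 4)
        labels = np.array([1] * 4 + [0] * 4)
        assert gs.idi(old, new, labels, n_boot=10)[0] == pytest.approx(1.0)

    def test_eight_subject_hand_means(self):
        old = np.array([0.2, 0.4, 0.5, 0.3, 0.6, 0.1, 0.3, 0.2])
        new = np.array([0.7, 0.5, 0.9, 0.4, 0.2, 0.3, 0.1, 0.4])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        # slope_new - slope_old = (0.625-0.25) - (0.35-0.3) = 0.325
        assert gs.idi(old, new, labels, n_boot=10)[0] == pytest.approx(0.325)

    def test_raw_scores_rejected(self):
        with pytest.raises(EvaluationError):
            gs.idi([1.5, 0.2], [0.1, 0.9], [1, 0])

    def test_rank_to_probability_mapping(self):
        p = gs.rank_to_probability([10.0, -5.0, 3.0])
        np.testing.assert_allclose(p, [5 / 6, 1 / 6, 3 / 6])


class TestDca:
    def test_treat_none_is_zero(self):
        d = gs.dca([0.3, 0.7], [0, 1], [0.2, 0.5])
        np.testing.assert_array_equal(d.net_benefit_none, 0.0)

    def test_small_threshold_approaches_prevalence(self):
        labels = np.array([1, 1, 0, 0, 0])
        d = gs.dca([0.9, 0.8, 0.7, 0.6, 0.5], labels, [0.001])
        assert d.net_benefit[0] == pytest.approx(0.4, abs=0.002)

    def test_ten_subject_hand_confusion_matrix(self):
        p = np.array([0.9, 0.8, 0.6, 0.4, 0.3, 0.7, 0.5, 0.2, 0.1, 0.35])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        d = gs.dca(p, labels, [0.25])
        # at 0.25: positives are p>=0.25 -> TP=4, FP=4; NB = 0.4 - 0.4/3
        assert d.net_benefit[0] == pytest.approx(0.4 - 0.4 * (0.25 / 0.75))

    def test_subject_permutation_invariance(self, rng):
        p = rng.uniform(size=30)
        labels = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        d1 = gs.dca(p, labels, [0.3, 0.6])
        d2 = gs.dca(p[perm], labels[perm], [0.3, 0.6])
        np.testing.assert_allclose(d1.net_benefit, d2.net_benefit)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(EvaluationError):
            gs.dca([0.5], [1], [0.0])


@pytest.fixture(scope="module")
def cohort_graph():
    cohort = gs.generate_cohort(gs.CohortSpec(n_patients=300, seed=21))
    records = gs.assign_splits(cohort.records, seed=21)
    return gs.build_graph(records, cohort.features)


class TestCompareModels:
    def test_model_compared_to_itself_is_null(self, cohort_graph):
        g = cohort_graph
        risks = np.linspace(0, 1, g.n_nodes)
        reports = gs.compare_models(
            {"a": risks, "b": risks}, {"OS": (g.os_time, g.os_event)},
            g.masks["train"], baseline="a", n_boot=30, seed=0)
        rep = reports["b"]["OS"]
        assert rep.nri == 0.0 and rep.idi == pytest.approx(0.0, abs=1e-12)
        base = reports["a"]["OS"]
        assert rep.dca_net_benefit == base.dca_net_benefit

    def test_stage_baseline_beats_chance_under_stage_effect(self):
        cohort = gs.generate_cohort(gs.CohortSpec(
            n_patients=800, effect_sizes=(0.8, 0.0), seed=5))
        records = gs.assign_splits(cohort.records, seed=5)
        g = gs.build_graph(records, cohort.features)
        base = gs.stage_baseline_risks(g.records)
        auc, _ = gs.auc_ci(base, g.os_time, g.os_event, n_boot=20, seed=0)
        assert auc > 0.55

    def test_report_stable_under_fixed_seed(self, cohort_graph):
        g = cohort_graph
        risks = np.sin(np.arange(g.n_nodes) * 0.7)
        base = gs.stage_baseline_risks(g.records)
        kw = dict(train_mask=g.masks["train"], baseline="base",
                  eval_mask=g.masks["test"], n_boot=50, seed=9)
        r1 = gs.compare_models({"m": risks, "base": base},
                               {"OS": (g.os_time, g.os_event)}, **kw)
        r2 = gs.compare_models({"m": risks, "base": base},
                               {"OS": (g.os_time, g.os_event)}, **kw)
        assert r1["m"]["OS"].to_dict() == r2["m"]["OS"].to_dict()
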