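import numpy as np
import pandas as pd
import pytest

from bridgenet import (
    PrognosticModel,
    SurvivalCohort,
    classify_by_correlation,
    cv_select_threshold,
    evaluate_prognosis,
    hierarchical_subgroups,
    identify_poorest_group,
    km_estimate,
    logrank_test,
    simulate_cohort,
    train_prognostic_model,
)
from bridgenet.prognosis import PrognosticError


def surv_frame(times, events, prefix="p"):
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events},
                        index=pd.Index(idx, name="sample")).astype(
        {"time": float, "event": int})


class TestHierarchicalSubgroups:
    def test_recovers_three_separated_blobs(self):
        rng = np.random.default_rng(0)
        centers = [np.zeros(10), np.full(10, 8.0), np.full(10, -8.0)]
        cols, data, truth = [], [], []
        for b, c in enumerate(centers):
            for j in range(30):
                cols.append(f"b{b}_{j}")
                data.append(c + rng.normal(0, 0.5, 10))
                truth.append(b)
        expr = pd.DataFrame(np.array(data).T, columns=cols)
        labels = hierarchical_subgroups(expr, k=3)
        # partition identical to ground truth up to renaming
        df = pd.DataFrame({"truth": truth, "label": labels.to_numpy()})
        assert df.groupby("truth")["label"].nunique().eq(1).all()
        assert labels.nunique() == 3

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        labels = hierarchical_subgroups(expr, k=4)
        assert labels.nunique() == 4

    def test_duplicate_samples_cocluster(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=6)
        expr = pd.DataFrame({"x1": base, "x2": base,
                             "y": base + 10, "z": base - 10})
        labels = hierarchical_subgroups(expr, k=3)
        assert labels["x1"] == labels["x2"]

    def test_k_below_two_rejected(self):
        expr = pd.DataFrame(np.eye(3))
        with pytest.raises(PrognosticError):
            hierarchical_subgroups(expr, k=1)


class TestKaplanMeier:
    def test_uncensored_steps_match_product_limit_by_hand(self):
        surv = surv_frame([1, 2, 3], [1, 1, 1])
        labels = pd.Series("g", index=surv.index)
        (curve,) = km_estimate(surv, labels).values()
        steps = dict(zip(curve["time"], curve["survival"]))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(1 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        surv = surv_frame([5, 8, 12], [0, 0, 0])
        (curve,) = km_estimate(surv, pd.Series("g", index=surv.index)).values()
        assert (curve["survival"] == 1.0).all()

    def test_mixed_censoring_matches_hand_computed_table(self):
        # six subjects: events at 1, 3, 5, 6; censored at 2 and 4
        # S(1)=5/6, S(3)=5/6*3/4, S(5)=...*1/2, S(6)=0
        surv = surv_frame([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
        (curve,) = km_estimate(surv, pd.Series("g", index=surv.index)).values()
        steps = dict(zip(curve["time"], curve["survival"]))
        assert steps[1.0] == pytest.approx(5 / 6)
        assert steps[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert steps[5.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        assert steps[6.0] == pytest.approx(0.0)

    def test_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, size=40)
        surv = surv_frame(times, np.ones(40, dtype=int))
        (curve,) = km_estimate(surv, pd.Series("g", index=surv.index)).values()
        for t, s in zip(curve["time"], curve["survival"]):
            if t == 0:
                continue
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_group_rejected(self):
        surv = surv_frame([1.0], [1])
        with pytest.raises(PrognosticError):
            km_estimate(surv, pd.Series([], dtype=object))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        surv = surv_frame([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=surv.index)
        stat, p = logrank_test(surv, labels)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_subject_toy_matches_hand_computed_o_minus_e(self):
        # group a events at 1 and 3, group b at 2 and 4; by hand:
        # O_a = 2, E_a = 1/2 + 1/3 + 1/2 = 4/3, V = 1/4 + 2/9 + 1/4 = 13/18
        # chi2 = (2/3)^2 / (13/18) = 8/13
        surv = surv_frame([1, 3, 2, 4], [1, 1, 1, 1])
        labels = pd.Series(["a", "a", "b", "b"], index=surv.index)
        stat, _ = logrank_test(surv, labels)
        assert stat == pytest.approx(8 / 13, abs=1e-10)

    def test_single_group_rejected(self):
        surv = surv_frame([1, 2], [1, 1])
        with pytest.raises(PrognosticError):
            logrank_test(surv, pd.Series(["a", "a"], index=surv.index))

    def test_invariant_under_group_relabeling_and_monotone_time_transform(self):
        rng = np.random.default_rng(4)
        surv = surv_frame(rng.exponential(10, 30), rng.integers(0, 2, 30))
        labels = pd.Series(rng.choice(["a", "b"], 30), index=surv.index)
        stat1, _ = logrank_test(surv, labels)
        stat2, _ = logrank_test(surv, labels.map({"a": "x", "b": "y"}))
        warped = surv.assign(time=np.sqrt(surv["time"]))
        stat3, _ = logrank_test(warped, labels)
        assert stat1 == pytest.approx(stat2)
        assert stat1 == pytest.approx(stat3)


class TestFastLogrank:
    def test_internal_sweep_statistic_matches_lifelines_backed_test(self):
        from bridgenet.prognosis import _two_group_logrank_p

        rng = np.random.default_rng(0)
        checked = 0
        while checked < 25:
            n = int(rng.integers(10, 80))
            times = np.round(rng.exponential(10, n), 1)  # rounding forces ties
            events = rng.integers(0, 2, n)
            mask = rng.random(n) < 0.5
            if mask.all() or not mask.any():
                continue
            surv = surv_frame(times, events)
            labels = pd.Series(np.where(mask, "a", "b"), index=surv.index)
            _, p_reference = logrank_test(surv, labels)
            p_fast = _two_group_logrank_p(times.astype(float), events, mask)
            assert p_fast == pytest.approx(p_reference, abs=1e-10)
            checked += 1


class TestPoorestGroup:
    def test_all_events_early_vs_none(self):
        surv = surv_frame([1, 1, 10, 10], [1, 1, 0, 0])
        labels = pd.Series(["a", "a", "b", "b"], index=surv.index)
        assert identify_poorest_group(surv, labels) == "a"

    def test_symmetric_groups_tie_to_smallest_id(self):
        surv = surv_frame([2, 5, 2, 5], [1, 1, 1, 1])
        labels = pd.Series([1, 1, 2, 2], index=surv.index)
        assert identify_poorest_group(surv, labels) == 1

    def test_highest_hazard_group_found_in_simulation(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            times = np.concatenate([
                rng.exponential(1 / 0.1, 100),
                rng.exponential(1 / 0.5, 100),
                rng.exponential(1 / 1.0, 100),
            ])
            surv = surv_frame(times, np.ones(300, dtype=int))
            labels = pd.Series([0] * 100 + [1] * 100 + [2] * 100, index=surv.index)
            hits += identify_poorest_group(surv, labels) == 2
        assert hits >= 9


class TestCorrelationClassifier:
    @pytest.fixture
    def model(self):
        markers = [f"M{i}" for i in range(6)]
        ref = pd.Series([1.0, -1.0, 2.0, -2.0, 0.5, -0.5], index=markers)
        return PrognosticModel(ref, threshold=0.3, markers=markers)

    def cohort_from_columns(self, columns, markers):
        expr = pd.DataFrame(columns, index=markers)
        surv = surv_frame(np.full(expr.shape[1], 10.0), np.ones(expr.shape[1], int),
                          prefix="q")
        expr.columns = surv.index
        return SurvivalCohort(surv, expr)

    def test_patient_equal_to_reference_is_poor(self, model):
        cohort = self.cohort_from_columns(
            {"c0": model.reference_profile.to_numpy()}, model.markers)
        assert classify_by_correlation(cohort, model).iloc[0] == "poor"

    def test_negated_reference_is_good(self, model):
        cohort = self.cohort_from_columns(
            {"c0": -model.reference_profile.to_numpy()}, model.markers)
        assert classify_by_correlation(cohort, model).iloc[0] == "good"

    def test_raising_threshold_shrinks_the_poor_set(self, model):
        rng = np.random.default_rng(5)
        cols = {f"c{i}": rng.normal(size=6) for i in range(40)}
        cohort = self.cohort_from_columns(cols, model.markers)
        sizes = []
        for t in np.arange(-0.9, 0.91, 0.2):
            m = PrognosticModel(model.reference_profile, float(np.round(t, 2)),
                                model.markers)
            sizes.append((classify_by_correlation(cohort, m) == "poor").sum())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_too_few_shared_markers_rejected(self, model):
        cohort = self.cohort_from_columns({"c0": [1.0, 2.0]}, ["M0", "M1"])
        with pytest.raises(PrognosticError):
            classify_by_correlation(cohort, model)

    def test_model_yaml_round_trip(self, model, tmp_path):
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = PrognosticModel.from_yaml(path)
        assert back.threshold == model.threshold
        assert list(back.reference_profile.loc[model.markers]) == list(
            model.reference_profile)


class TestThresholdSelection:
    def test_degenerate_grid_returns_its_only_value(self):
        cohort, _ = simulate_cohort(n_patients=60, seed=6)
        t, best = cv_select_threshold(cohort, list(cohort.expression.index),
                                      grid=[-1.0], repeats=3, seed=0)
        assert t == -1.0 and set(best) == {-1.0}

    def test_fixed_seed_reproducible(self):
        cohort, _ = simulate_cohort(n_patients=80, seed=7)
        markers = list(cohort.expression.index)
        t1, _ = cv_select_threshold(cohort, markers, repeats=3, seed=5)
        t2, _ = cv_select_threshold(cohort, markers, repeats=3, seed=5)
        assert t1 == t2

    def test_planted_signature_recovered_across_seeds(self):
        hits = 0
        for seed in range(5):
            train, _ = simulate_cohort(n_patients=150, hazard_ratio=4.0, seed=seed)
            model = train_prognostic_model(train, list(train.expression.index),
                                           repeats=5, seed=seed)
            test, _ = simulate_cohort(n_patients=150, hazard_ratio=4.0,
                                      seed=seed + 1000, sample_prefix="Q")
            labels = classify_by_correlation(test, model)
            if labels.nunique() == 2:
                p, _ = evaluate_prognosis(test, labels)
                hits += p < 0.05
        assert hits >= 4


class TestEvaluation:
    def test_survival_determining_labels_give_small_p(self):
        cohort, truth = simulate_cohort(n_patients=200, hazard_ratio=4.0,
                                        seed=8)
        status = pd.Series(
            ["poor" if s in set(truth.poor_samples) else "good"
             for s in cohort.samples], index=cohort.samples)
        p, curves = evaluate_prognosis(cohort, status)
        assert p < 0.01
        assert set(curves) == {"good", "poor"}

    def test_covariate_column_can_drive_the_comparison(self):
        # mutation-status style categorical covariate used directly as labels
        cohort, truth = simulate_cohort(n_patients=120, hazard_ratio=3.0, seed=9)
        cov = pd.DataFrame({"mut": ["MT" if s in set(truth.poor_samples) else "WT"
                                    for s in cohort.samples]}, index=cohort.samples)
        cohort = SurvivalCohort(cohort.survival, cohort.expression, cov)
        p, _ = evaluate_prognosis(cohort, cohort.covariates["mut"])
        assert p < 0.05

    def test_single_label_rejected(self):
        cohort, _ = simulate_cohort(n_patients=30, seed=10)
        with pytest.raises(PrognosticError):
            evaluate_prognosis(cohort, pd.Series("poor", index=cohort.samples))
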