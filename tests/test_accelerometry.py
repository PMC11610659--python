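"""ODBA, behaviour classification, activity budgets and daily-ODBA models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fearscape import solar
from fearscape.accelerometry import (
    build_budgets,
    build_odba_daily,
    compute_odba,
    fit_budget_model,
    fit_odba_model,
    logit_shift,
    train_behavior_classifier,
)
from fearscape.config import SimulationConfig
from fearscape.simulate import (
    generate_training_bursts,
    simulate_budget_counts,
    simulate_odba_days,
)


class TestOdba:
    def test_constant_burst_zero(self):
        b = {"x": [1.0] * 5, "y": [2.0] * 5, "z": [-1.0] * 5}
        assert compute_odba(b) == 0.0

    def test_analytic_two_sample(self):
        assert compute_odba({"x": [1, -1], "y": [0, 0], "z": [0, 0]}) \
            == pytest.approx(1.0)

    def test_matches_brute_force_mad_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 200)
            b = {ax: rng.normal(size=n) for ax in "xyz"}
            # independent oracle: per-axis mean absolute deviation, summed
            oracle = sum(np.abs(np.asarray(b[ax]) - np.mean(b[ax])).mean()
                         for ax in "xyz")
            assert compute_odba(b) == pytest.approx(oracle, abs=1e-12)

    def test_too_short_burst_rejected(self):
        with pytest.raises(ValueError):
            compute_odba({"x": [1.0], "y": [1.0], "z": [1.0]})

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-4, 4), min_size=2, max_size=40),
           st.floats(0.1, 10.0), st.randoms(use_true_random=False))
    def test_permutation_invariant_and_scale_equivariant(self, xs, c, rnd):
        ys = list(xs)[::-1]
        zs = [0.0] * len(xs)
        base = compute_odba({"x": xs, "y": ys, "z": zs})
        perm = list(xs)
        rnd.shuffle(perm)
        assert compute_odba({"x": perm, "y": ys, "z": zs}) == pytest.approx(
            compute_odba({"x": xs, "y": ys, "z": zs}), rel=1e-9)
        scaled = compute_odba({"x": [c * v for v in xs],
                               "y": [c * v for v in ys], "z": zs})
        assert scaled == pytest.approx(c * base, rel=1e-9)


@pytest.fixture(scope="module")
def small_training():
    cfg = SimulationConfig(seed=6, behavior_counts={
        "walking": 60, "grazing": 200, "alert": 60, "resting": 50,
        "flying": 200})
    return generate_training_bursts(cfg)


class TestClassifier:

    def test_separable_classes_perfect_holdout(self, small_training):
        clf = train_behavior_classifier(small_training, seed=0)
        assert clf.accuracy == 1.0
        assert clf.confusion.to_numpy().sum() == clf.n_test

    def test_shuffled_labels_near_prior(self, small_training):
        shuffled = small_training.copy()
        rng = np.random.default_rng(4)
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        clf = train_behavior_classifier(shuffled, seed=0)
        prior = shuffled["label"].value_counts(normalize=True).max()
        assert clf.accuracy < prior + 0.1

    def test_single_class_rejected(self, small_training):
        one = small_training[small_training["label"] == "flying"]
        with pytest.raises(ValueError):
            train_behavior_classifier(one)

    def test_collapse_to_analysis_behaviors(self, small_training):
        clf = train_behavior_classifier(small_training, seed=0)
        out = clf.predict(small_training.head(100))
        assert set(out["behavior"]) <= {"walking", "grazing", "stationary", "flying"}


def _burst_table(n_per_period, days=12, bird="A"):
    """Hourly-ish classified bursts over `days` days (day + night)."""
    rows = []
    for d in range(days):
        date = pd.Timestamp(2021, 11, 1) + pd.Timedelta(days=d)
        for i in range(n_per_period):
            rows.append((bird, date + pd.Timedelta(hours=11) + pd.Timedelta(minutes=20 * i),
                         "grazing" if i % 3 else "flying"))
            rows.append((bird, date + pd.Timedelta(hours=22) + pd.Timedelta(minutes=20 * i),
                         "stationary"))
    return pd.DataFrame(rows, columns=["individual_id", "timestamp", "behavior"])


class TestBudgets:
    def test_five_burst_period_excluded(self):
        tab = _burst_table(5)
        assert build_budgets(tab).empty

    def test_proportions(self):
        tab = _burst_table(10)
        out = build_budgets(tab)
        day = out[~out["is_night"]]
        assert (day["n_bursts"] == 10).all()
        # i % 3 pattern: indices 0,3,6,9 are flying -> 4 of 10
        assert (day["bursts_flying"] == 4).all()
        assert (day["bursts_grazing"] == 6).all()

    def test_counts_sum_to_n(self):
        out = build_budgets(_burst_table(10))
        total = (out["bursts_grazing"] + out["bursts_stationary"]
                 + out["bursts_flying"] + out["bursts_walking"])
        assert (total == out["n_bursts"]).all()

    def test_night_inherits_previous_day_disturbance(self):
        tab = _burst_table(8, days=12)
        rec = pd.DataFrame({
            "individual_id": "A",
            "date": pd.date_range("2021-11-01", periods=12),
            "disturbed": [False, True] + [False] * 10,
            "night_after_disturbed": [False, True] + [False] * 10})
        out = build_budgets(tab, rec)
        night = out[out["is_night"]].set_index("date")
        assert bool(night.loc[pd.Timestamp("2021-11-02"), "disturbed"])
        assert not night.loc[pd.Timestamp("2021-11-03"), "disturbed"]

    def test_under_ten_days_individual_excluded(self):
        tab = _burst_table(8, days=6)
        assert build_budgets(tab).empty


class TestBudgetModel:
    def test_logit_shift_published_examples(self):
        assert logit_shift(0.446, -0.073) == pytest.approx(0.428, abs=5e-4)
        assert logit_shift(0.053, 0.089) == pytest.approx(0.058, abs=5e-4)

    def test_recovers_injected_shot_effect(self):
        b = simulate_budget_counts(shot_effect=-0.3, seed=3,
                                   n_individuals=12, n_days=50
                                   ).rename(columns={"k_bursts": "bursts_grazing"})
        comp, fits = fit_budget_model(b, "grazing")
        term = [t for t in fits["global"].params.index
                if "shot_f" in t and ":" not in t][0]
        est = fits["global"].params[term]
        se = fits["global"].se[term]
        assert abs(est - (-0.3)) < 2.5 * se

    def test_null_ci_coverage(self):
        cover, reps = 0, 40
        for r in range(reps):
            b = simulate_budget_counts(
                shot_effect=0.0, seed=900 + r, n_individuals=6, n_days=25
            ).rename(columns={"k_bursts": "bursts_grazing"})
            _, fits = fit_budget_model(b, "grazing")
            f = fits["no_interaction"]
            term = [t for t in f.params.index if "shot_f" in t][0]
            cover += abs(f.params[term]) <= 1.96 * f.se[term]
        assert cover >= 0.9 * reps

    def test_dispersion_large_when_binomial(self):
        """Beta-binomial nests binomial: on binomial data the estimated
        dispersion theta is large."""
        b = simulate_budget_counts(theta=1e9, seed=5, n_individuals=8,
                                   n_days=40).rename(
            columns={"k_bursts": "bursts_grazing"})
        _, fits = fit_budget_model(b, "grazing")
        assert fits["global"].theta > 200

    def test_degenerate_proportions_rejected(self):
        b = simulate_budget_counts(seed=1).rename(
            columns={"k_bursts": "bursts_grazing"})
        b["bursts_grazing"] = 0
        comp, fits = fit_budget_model(b, "grazing")
        assert not fits
        assert comp["status"].str.contains("degenerate").all()


class TestOdbaModel:
    def test_bursts_drive_odba_and_null_shot(self):
        od = simulate_odba_days(shot_effect=0.0, bursts_coef=0.02, seed=6,
                                n_individuals=10, n_days=60)
        comp, fits = fit_odba_model(od)
        g = fits["global"]
        assert g.params["n_bursts"] > 0
        term = [t for t in g.params.index if "shot2" in t and ":" not in t][0]
        assert abs(g.params[term]) <= 2.5 * g.se()[term]

    def test_concave_seasonal_trend_negative_date2(self):
        od = simulate_odba_days(date2_coef=-3.0, seed=7, n_individuals=10,
                                n_days=120)
        comp, fits = fit_odba_model(od)
        top = comp.iloc[0]["model"]
        assert fits[top].params["date_s2"] < 0
        assert fits[top].params["date_s2"] == pytest.approx(-3.0, abs=1.0)

    def test_doubling_response_shifts_intercept_by_log2(self):
        od = simulate_odba_days(seed=8, n_individuals=6, n_days=40)
        _, f1 = fit_odba_model(od)
        od2 = od.copy()
        od2["total_odba"] *= 2.0
        _, f2 = fit_odba_model(od2)
        a, b = f1["global"].params, f2["global"].params
        assert b["Intercept"] - a["Intercept"] == pytest.approx(np.log(2), abs=1e-6)
        others = [t for t in a.index if t != "Intercept"]
        np.testing.assert_allclose(b[others], a[others], atol=1e-6)

    def test_zero_rows_rejected(self):
        od = simulate_odba_days(seed=9, n_individuals=3, n_days=15)
        od.loc[od.index[0], "total_odba"] = 0.0
        from fearscape.accelerometry import fit_odba_global

        with pytest.raises(ValueError, match="gamma"):
            fit_odba_global(od, use_gee=False)


class TestDailyBuild:
    def test_odba_daily_from_bursts(self, study):
        from fearscape.simulate import generate_acc_bursts

        bursts = generate_acc_bursts(study["tracks"], config=study["config"],
                                     every_nth_fix=2)
        bursts = bursts[bursts["individual_id"].isin(
            bursts["individual_id"].unique()[:4])].copy()
        bursts["odba"] = [compute_odba(r)
                          for r in bursts[["x", "y", "z"]].to_dict("records")]
        daily = build_odba_daily(bursts)
        assert (daily["total_odba"] > 0).all()
        assert {"species", "sex", "n_bursts"} <= set(daily.columns)
        # daytime-only sums: n_bursts below the full day's schedule
        assert daily["n_bursts"].max() <= 12
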