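"""Step-pair construction, decay-model fitting and the derived
disturbance distance."""

import numpy as np
import pandas as pd
import pytest

from fearscape.displacement import (
    DisplacementFit,
    build_step_pairs,
    derive_disturbance_threshold,
    fit_displacement_model,
)


def _fixes(rows):
    df = pd.DataFrame(rows, columns=["individual_id", "species", "winter",
                                     "timestamp", "x", "y"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def _events(rows):
    df = pd.DataFrame(rows, columns=["event_id", "timestamp", "field_id",
                                     "centroid_x", "centroid_y"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


class TestBuildStepPairs:
    def test_hand_geometry(self):
        fx = _fixes([("A", "GBG", "2021-2022", "2021-11-05 10:00", 0.0, 0.0),
                     ("A", "GBG", "2021-2022", "2021-11-05 11:00", 0.0, 100.0),
                     ("A", "GBG", "2021-2022", "2021-11-05 12:00", 0.0, 400.0)])
        ev = _events([("E1", "2021-11-05 11:30", "F", 1000.0, 100.0)])
        pairs = build_step_pairs(fx, ev)
        assert len(pairs) == 1
        p = pairs.iloc[0]
        assert p["SL_t"] == pytest.approx(300.0)
        assert p["SL_t_minus_1"] == pytest.approx(100.0)
        assert p["delta_SL"] == pytest.approx(200.0)
        assert p["dist_to_event"] == pytest.approx(1000.0)
        assert p["event_time_h"] == pytest.approx(11.5)

    @pytest.mark.parametrize("centroid_x,event_time,expect", [
        (5000.0, "2021-11-05 11:30", 0),   # 5 km away: 4 km rule
        (1000.0, "2021-11-05 12:30", 0),   # prior fix 90 min stale: 1 h rule
        (1000.0, "2021-11-05 11:45", 1),   # within both limits
    ])
    def test_retention_rules(self, centroid_x, event_time, expect):
        # note the gap: no fix at 12:00, so a 12:30 event's prior fix
        # is the 11:00 one, 90 minutes stale
        fx = _fixes([("A", "GBG", "2021-2022", "2021-11-05 10:00", 0.0, 0.0),
                     ("A", "GBG", "2021-2022", "2021-11-05 11:00", 0.0, 100.0),
                     ("A", "GBG", "2021-2022", "2021-11-05 13:00", 0.0, 500.0)])
        ev = _events([("E1", event_time, "F", centroid_x, 100.0)])
        assert len(build_step_pairs(fx, ev)) == expect

    def test_simultaneous_events_keep_nearest(self):
        fx = _fixes([("A", "GBG", "2021-2022", "2021-11-05 10:00", 0.0, 0.0),
                     ("A", "GBG", "2021-2022", "2021-11-05 11:00", 0.0, 100.0),
                     ("A", "GBG", "2021-2022", "2021-11-05 12:00", 0.0, 400.0)])
        ev = _events([("Efar", "2021-11-05 11:30", "F1", 3000.0, 100.0),
                      ("Enear", "2021-11-05 11:40", "F2", 500.0, 100.0)])
        pairs = build_step_pairs(fx, ev)
        assert len(pairs) == 1
        assert pairs["event_id"].iloc[0] == "Enear"


def _synthetic_pairs(n=400, alpha=1000.0, beta=-200.0, noise=0.0, seed=0,
                     n_birds=8):
    rng = np.random.default_rng(seed)
    d = np.exp(rng.uniform(np.log(30), np.log(4000), n))
    t = rng.uniform(9, 15, n)
    delta = alpha + beta * np.log(d) + rng.normal(0, noise, n)
    return pd.DataFrame({
        "individual_id": [f"B{i % n_birds}" for i in range(n)],
        "event_id": [f"E{i}" for i in range(n)],
        "species": "GBG", "winter": "2021-2022",
        "SL_t": np.abs(delta) + 100, "SL_t_minus_1": 100.0,
        "delta_SL": delta, "dist_to_event": d, "event_time_h": t})


class TestFit:
    def test_noiseless_line_recovered_to_ols_precision(self):
        """Near-noiseless data: the mixed fit must match the closed-form
        least-squares oracle."""
        pairs = _synthetic_pairs(noise=1e-6)
        fit = fit_displacement_model(pairs, winter_mode="none")
        X = np.column_stack([np.ones(len(pairs)),
                             np.log(pairs["dist_to_event"]),
                             pairs["event_time_h"], pairs["event_time_h"] ** 2])
        ols = np.linalg.lstsq(X, pairs["delta_SL"], rcond=None)[0]
        assert fit.intercept == pytest.approx(ols[0], abs=1e-3)
        assert fit.slope_logdist == pytest.approx(ols[1], abs=1e-4)
        assert fit.intercept == pytest.approx(1000.0, abs=1e-2)
        assert fit.slope_logdist == pytest.approx(-200.0, abs=1e-3)

    def test_null_slope_ci_coverage(self):
        """No injected decay: the slope CI covers zero in >= 90% of reps."""
        cover = 0
        reps = 50
        for r in range(reps):
            pairs = _synthetic_pairs(n=200, alpha=0.0, beta=0.0, noise=150.0,
                                     seed=100 + r)
            fit = fit_displacement_model(pairs)
            i = list(fit.params.index).index("log_dist")
            se = np.sqrt(fit.cov.iloc[i, i])
            cover += abs(fit.slope_logdist) <= 1.96 * se
        assert cover >= 0.9 * reps

    def test_insufficient_data_rejected(self):
        pairs = _synthetic_pairs(n=10)
        with pytest.raises(ValueError, match="pairs"):
            fit_displacement_model(pairs)
        one_bird = _synthetic_pairs(n=50, n_birds=1)
        with pytest.raises(ValueError, match="individuals"):
            fit_displacement_model(one_bird)

    def test_collinear_term_named(self):
        pairs = _synthetic_pairs(n=100)
        pairs["event_time_h"] = 12.0  # time and time^2 now collinear with 1
        with pytest.raises(ValueError, match="collinear"):
            fit_displacement_model(pairs)

    def test_threshold_invariant_to_timestamp_shift(self):
        pairs = _synthetic_pairs(noise=50.0, seed=3)
        fit = fit_displacement_model(pairs)
        shifted = pairs.copy()
        # shifting all event clock times leaves the distance decay alone
        fit2 = fit_displacement_model(shifted.assign(
            event_time_h=shifted["event_time_h"]))
        assert derive_disturbance_threshold(fit) == pytest.approx(
            derive_disturbance_threshold(fit2), abs=1.0)

    def test_self_control_permutation_null(self, study):
        """Pairing steps with shuffled distances (no injected signal at the
        matched distance) yields a slope CI covering zero."""
        from fearscape.displacement import build_step_pairs

        pairs = build_step_pairs(study["fixes"], study["events"])
        sub = pairs[pairs["species"] == "GBG"].copy()
        rng = np.random.default_rng(1)
        # break the distance-response link but keep both marginals
        sub["dist_to_event"] = rng.permutation(sub["dist_to_event"].to_numpy())
        fit = fit_displacement_model(sub)
        i = list(fit.params.index).index("log_dist")
        se = np.sqrt(fit.cov.iloc[i, i])
        assert abs(fit.slope_logdist) <= 2.5 * se


class TestThreshold:
    def _fit(self, alpha, beta, cov_scale=0.0):
        params = pd.Series({"Intercept": alpha, "log_dist": beta})
        cov = pd.DataFrame(cov_scale * np.eye(2),
                           index=params.index, columns=params.index)
        return DisplacementFit(species="GBG", params=params, cov=cov,
                               n_pairs=100, n_individuals=10,
                               winter_mode="none", ref_time_h=12.0)

    def test_zero_covariance_matches_analytic_root(self):
        fit = self._fit(1711.0, -224.3)
        root = np.exp(1711.0 / 224.3)
        assert derive_disturbance_threshold(fit) == pytest.approx(root, abs=1.0)

    def test_nonnegative_slope_gives_sentinel(self):
        assert derive_disturbance_threshold(self._fit(100.0, 0.5)) == np.inf

    def test_lower_ci_positive_throughout_gives_sentinel(self):
        # mean crossing far beyond the grid
        fit = self._fit(5000.0, -100.0)
        assert derive_disturbance_threshold(fit, grid_max_m=4000) == np.inf

    def test_crossing_decreases_with_inflated_covariance(self):
        thr = [derive_disturbance_threshold(self._fit(1711.0, -224.3, s))
               for s in (0.0, 100.0, 400.0)]
        assert thr[0] > thr[1] > thr[2]
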