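"""Synthetic tracking, shooting and accelerometer data.

The generator emulates the data-generating process the analyses assume:

* roost-forage daily movement — birds sit on a night roost, commute to a
  home farm at dawn, take gamma-distributed foraging steps tethered to
  the farm, and return to the roost at dusk;
* shooting events on designated fields during daylight, targeted at
  fields where geese currently are (as marksmen do);
* a displacement response injected into the step following each event:
  for every bird within the exposure radius the disturbed step length is
  its previous (control) step plus the species decay law
  ``b0 + b1*ln(dist)`` plus noise, so fitting the displacement model to
  generator output recovers the configured coefficients;
* tri-axial accelerometer bursts whose class-conditional signal
  statistics are configured per behaviour.

Direct simulators for the daily-distance, activity-budget and daily-ODBA
models (gamma / beta-binomial with AR1 day series) live here too; they
generate at the response scale so model recovery can be tested at any
sample size without paying for full track generation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from fearscape import solar
from fearscape.config import (
    BEHAVIOR_CLASSES,
    SimulationConfig,
    winter_label,
)
from fearscape.landscape import Landscape

TRACK_COLUMNS = ["individual_id", "species", "sex", "timestamp", "x", "y"]

#: default probability of each behaviour class for day and night bursts
DEFAULT_BEHAVIOR_SCHEDULE = {
    "day": {"grazing": 0.55, "walking": 0.12, "alert": 0.18, "resting": 0.10, "flying": 0.05},
    "night": {"resting": 0.80, "alert": 0.12, "grazing": 0.06, "flying": 0.02, "walking": 0.00},
}


def _winter_dates(config: SimulationConfig, w: int) -> pd.DatetimeIndex:
    y = config.first_winter_year + w
    start = pd.Timestamp(y, *config.start_month_day)
    # an end month before the start month belongs to the following spring
    end_year = y + 1 if config.end_month_day < config.start_month_day else y
    end = pd.Timestamp(end_year, *config.end_month_day)
    return pd.date_range(start, end, freq="D")


def _daylight_table(config: SimulationConfig) -> pd.DataFrame:
    """Sunrise/sunset per simulated date."""
    rows = []
    for w in range(config.n_winters):
        for d in _winter_dates(config, w):
            sr, ss = solar.daylight_window(d)
            rows.append((d, sr, ss))
    return pd.DataFrame(rows, columns=["date", "sunrise", "sunset"]).set_index("date")


def generate_tracks(landscape: Landscape, config: SimulationConfig) -> pd.DataFrame:
    """Per-individual GPS fixes spanning each simulated winter.

    Night fixes cluster at the bird's roost; day fixes are a tethered
    gamma-step random walk around a home farm, with the per-day step
    mean calibrated so undisturbed cumulative daytime distance matches
    the species target.  Returns a tidy frame with columns
    ``individual_id, species, sex, timestamp, x, y`` sorted by
    individual then time.
    """
    if config.n_individuals_per_species == 0:
        warnings.warn("zero individuals configured; returning empty track table")
        return pd.DataFrame(columns=TRACK_COLUMNS)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    farm_ids = sorted(landscape.farms)
    centroids = {f: np.array(landscape.farms[f].centroid.coords[0]) for f in farm_ids}
    x0, y0, x1, y1 = landscape.extent
    k = config.step_gamma_shape
    R = config.farm_radius_m

    frames = []
    for species in sorted(config.species_params):
        daily_target_m = config.species_params[species].daily_km_undisturbed * 1000.0
        for b in range(config.n_individuals_per_species):
            bird = f"{species}{b + 1:02d}"
            sex = "M" if b % 2 == 0 else "F"
            roost = np.array(landscape.roosts[b % len(landscape.roosts)].coords[0])
            # a small pool of familiar farms, nearest to the roost
            by_dist = sorted(farm_ids, key=lambda f: np.sum((centroids[f] - roost) ** 2))
            pool = by_dist[: max(3, len(farm_ids) // 5)]
            farm = pool[rng.integers(len(pool))]

            ts_parts = []
            for w in range(config.n_winters):
                dates = _winter_dates(config, w)
                ts_parts.append(pd.date_range(
                    dates[0], dates[-1] + pd.Timedelta(days=1),
                    freq=f"{config.fix_interval_min}min", inclusive="left"))
            ts = ts_parts[0].append(ts_parts[1:]) if len(ts_parts) > 1 else ts_parts[0]
            day_mask = solar.is_daytime(ts)
            n = len(ts)
            xy = np.empty((n, 2))
            # night fixes: roost with GPS-scale jitter
            n_night = int((~day_mask).sum())
            xy[~day_mask] = roost + rng.normal(0, config.roost_jitter_m, (n_night, 2))

            dates_arr = ts.normalize()
            day_dates = np.unique(dates_arr[day_mask])
            # one winter-long step mean: daily distance then tracks day
            # length around the configured winter-average target
            mean_steps = max(
                float(day_mask.sum()) / max(len(day_dates), 1) - 1.0, 1.0)
            step_mean = daily_target_m / mean_steps
            for d in day_dates:
                idx = np.nonzero((dates_arr == d) & day_mask)[0]
                if rng.random() < config.farm_switch_prob:
                    farm = pool[rng.integers(len(pool))]
                c = centroids[farm]
                m = len(idx)
                offset = rng.normal(0, 60.0, 2)
                pts = np.empty((m, 2))
                pts[0] = c + offset
                lengths = rng.gamma(k, step_mean / k, size=max(m - 1, 0))
                angles = rng.uniform(0, 2 * np.pi, size=max(m - 1, 0))
                for i in range(m - 1):
                    step = lengths[i] * np.array([np.cos(angles[i]), np.sin(angles[i])])
                    prop = offset + step
                    if prop @ prop > R * R:
                        # bounce: flip the radial component, preserving length
                        r = offset / max(np.hypot(*offset), 1e-9)
                        step = step - 2.0 * (step @ r) * r
                        prop = offset + step
                        if prop @ prop > R * R:
                            step = lengths[i] * -offset / max(np.hypot(*offset), 1e-9)
                            prop = offset + step
                    offset = prop
                    pts[i + 1] = c + offset
                xy[idx] = pts

            xy[:, 0] = np.clip(xy[:, 0], x0, x1)
            xy[:, 1] = np.clip(xy[:, 1], y0, y1)
            frames.append(pd.DataFrame({
                "individual_id": bird, "species": species, "sex": sex,
                "timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]}))

    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["individual_id", "timestamp"], ignore_index=True)


def generate_shooting_log(
    landscape: Landscape,
    tracks: pd.DataFrame,
    config: SimulationConfig,
):
    """Shooting events plus tracks with the displacement response injected.

    Events are placed on shooting-designated fields during daylight
    (at least 2 h from sunrise/sunset so the surrounding steps are
    foraging steps), on the field nearest a randomly chosen bird.  For
    every bird whose latest fix is within the exposure radius of the
    event centroid, the following step is rewritten to length
    ``max(0, SL_prev + b0 + b1*ln(dist) + noise)`` in a direction away
    from the event, and the rest of that day's fixes are shifted with
    it (the flock resettles elsewhere).

    Returns ``(events, perturbed_tracks, truth)`` where ``truth`` has one
    row per perturbed (bird, event) with the injected displacement —
    ground truth for recovery tests.
    """
    event_cols = ["event_id", "timestamp", "field_id", "centroid_x", "centroid_y",
                  "n_shots", "n_killed"]
    if config.shooting_rate == 0 or tracks.empty:
        return (pd.DataFrame(columns=event_cols), tracks.copy(),
                pd.DataFrame(columns=["event_id", "individual_id", "dist_m",
                                      "injected_delta_m", "expected_delta_m"]))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    daylight = _daylight_table(config)
    x0, y0, x1, y1 = landscape.extent
    shoot_cent = {f: np.array(landscape.fields[f].centroid.coords[0])
                  for f in landscape.shooting_fields}
    shoot_ids = list(landscape.shooting_fields)
    cent_arr = np.array([shoot_cent[f] for f in shoot_ids])

    # mutable per-bird arrays
    birds = {}
    for bird, grp in tracks.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp")
        birds[bird] = {
            "ts": grp["timestamp"].to_numpy(),
            "xy": grp[["x", "y"]].to_numpy().copy(),
            "day": solar.is_daytime(grp["timestamp"]),
            "species": grp["species"].iloc[0],
            "index": grp.index.to_numpy(),
        }
    bird_ids = sorted(birds)

    events, truth = [], []
    eid = 0
    for date, row in daylight.iterrows():
        lo = row["sunrise"] + pd.Timedelta(hours=2)
        hi = row["sunset"] - pd.Timedelta(hours=2)
        if hi <= lo:
            continue
        day_times: list = []
        for _ in range(rng.poisson(config.shooting_rate)):
            minutes = int((hi - lo).total_seconds() // 60)
            # same-day events at least 3 h apart: one field is not shot
            # over repeatedly, and a bird's control step never overlaps
            # a previous event's displacement
            ev_ts = None
            for _try in range(10):
                cand = lo + pd.Timedelta(minutes=int(rng.integers(minutes + 1)))
                if all(abs((cand - t).total_seconds()) >= 3 * 3600 for t in day_times):
                    ev_ts = cand
                    break
            if ev_ts is None:
                continue
            day_times.append(ev_ts)
            ev_np = np.datetime64(ev_ts)
            # target the field nearest a randomly chosen bird's current fix
            tgt = birds[bird_ids[rng.integers(len(bird_ids))]]
            i = np.searchsorted(tgt["ts"], ev_np, side="right") - 1
            if i < 0:
                continue
            pos = tgt["xy"][i]
            fid = shoot_ids[int(np.argmin(np.sum((cent_arr - pos) ** 2, axis=1)))]
            cx, cy = shoot_cent[fid]
            eid += 1
            n_shots = 1 + rng.poisson(3)
            events.append((f"E{eid:04d}", ev_ts, fid, cx, cy,
                           n_shots, rng.binomial(n_shots, 0.2)))

            for bird in bird_ids:
                st = birds[bird]
                i = np.searchsorted(st["ts"], ev_np, side="right") - 1
                if i < 1 or i + 1 >= len(st["ts"]):
                    continue
                # pre-event fix must be recent and part of a daytime series
                age_h = (ev_np - st["ts"][i]) / np.timedelta64(1, "h")
                if age_h > 1.0 or not (st["day"][i] and st["day"][i + 1]):
                    continue
                dx, dy = st["xy"][i] - (cx, cy)
                dist = float(np.hypot(dx, dy))
                if dist > config.exposure_radius_m:
                    continue
                p = config.species_params[st["species"]]
                m = p.displacement_intercept + p.displacement_slope * np.log(max(dist, 1.0))
                sl_prev = float(np.hypot(*(st["xy"][i] - st["xy"][i - 1])))
                target = max(0.0, sl_prev + m + rng.normal(0, config.displacement_noise_sd))
                away = np.arctan2(dy, dx)
                newpos = None
                for _try in range(20):
                    theta = away + rng.uniform(-np.pi / 2, np.pi / 2)
                    cand = st["xy"][i] + target * np.array([np.cos(theta), np.sin(theta)])
                    if x0 <= cand[0] <= x1 and y0 <= cand[1] <= y1:
                        newpos = cand
                        break
                if newpos is None:
                    theta = away + rng.uniform(-np.pi / 2, np.pi / 2)
                    cand = st["xy"][i] + target * np.array([np.cos(theta), np.sin(theta)])
                    newpos = np.clip(cand, (x0, y0), (x1, y1))
                shift = newpos - st["xy"][i + 1]
                # relocate the remainder of the day's foraging with the bird
                j = i + 1
                day_end = j
                while day_end < len(st["ts"]) and st["day"][day_end] and \
                        st["ts"][day_end].astype("datetime64[D]") == ev_np.astype("datetime64[D]"):
                    day_end += 1
                st["xy"][j:day_end] += shift
                st["xy"][j:day_end, 0] = np.clip(st["xy"][j:day_end, 0], x0, x1)
                st["xy"][j:day_end, 1] = np.clip(st["xy"][j:day_end, 1], y0, y1)
                realized = float(np.hypot(*(st["xy"][j] - st["xy"][i])))
                truth.append((f"E{eid:04d}", bird, dist,
                              realized - sl_prev, m))

    out = tracks.copy()
    for bird in bird_ids:
        st = birds[bird]
        out.loc[st["index"], ["x", "y"]] = st["xy"]
    events_df = pd.DataFrame(events, columns=event_cols)
    truth_df = pd.DataFrame(
        truth, columns=["event_id", "individual_id", "dist_m",
                        "injected_delta_m", "expected_delta_m"])
    return events_df, out, truth_df


# -- accelerometer bursts ---------------------------------------------

def _burst_samples(cls: str, n: int, params: dict, rng) -> tuple:
    p = params[cls]
    mx, my, mz = p["mean"]
    sd = p["sd"]
    return (mx + rng.normal(0, sd, n), my + rng.normal(0, sd, n), mz + rng.normal(0, sd, n))


def generate_training_bursts(config: SimulationConfig) -> pd.DataFrame:
    """Labelled bursts with exactly the configured per-class counts.

    Emulates a video-validated training set; one row per burst with
    object-array columns ``x, y, z`` and the true ``label``.
    """
    missing = set(BEHAVIOR_CLASSES) - set(config.behavior_counts)
    if missing:
        raise ValueError(f"behavior_counts missing classes: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    rows = []
    for cls in BEHAVIOR_CLASSES:
        for i in range(config.behavior_counts[cls]):
            x, y, z = _burst_samples(cls, config.burst_n_samples,
                                     config.behavior_signal_params, rng)
            rows.append((f"train{len(rows) + 1:05d}", cls, x, y, z))
    df = pd.DataFrame(rows, columns=["burst_id", "label", "x", "y", "z"])
    df["individual_id"] = "training"
    df["timestamp"] = pd.NaT
    return df


def generate_acc_bursts(
    tracks: pd.DataFrame,
    behavior_schedule: dict | None = None,
    config: SimulationConfig | None = None,
    every_nth_fix: int = 1,
) -> pd.DataFrame:
    """One labelled burst per GPS fix, behaviour drawn from a schedule.

    ``behavior_schedule`` maps ``"day"``/``"night"`` to class
    probabilities; the defaults put geese mostly grazing by day and
    resting on the roost by night.  ``every_nth_fix`` thins the burst
    schedule for large tracks.
    """
    config = config or SimulationConfig()
    schedule = behavior_schedule or DEFAULT_BEHAVIOR_SCHEDULE
    for key in ("day", "night"):
        missing = set(schedule.get(key, {})) - set(config.behavior_signal_params)
        if missing:
            raise ValueError(f"schedule classes lack signal params: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    sub = tracks.iloc[::max(1, every_nth_fix)].reset_index(drop=True)
    day = solar.is_daytime(sub["timestamp"])
    n = len(sub)

    labels = np.empty(n, dtype=object)
    for mask, key in ((day, "day"), (~day, "night")):
        sched = schedule[key]
        classes = sorted(sched)
        probs = np.array([sched[c] for c in classes], float)
        labels[mask] = rng.choice(classes, size=int(mask.sum()), p=probs / probs.sum())

    ns = config.burst_n_samples
    xs = np.empty(n, dtype=object)
    ys = np.empty(n, dtype=object)
    zs = np.empty(n, dtype=object)
    for cls in sorted(set(labels)):
        idx = np.nonzero(labels == cls)[0]
        p = config.behavior_signal_params[cls]
        mx, my, mz = p["mean"]
        block = rng.normal(0, p["sd"], size=(len(idx), 3, ns))
        for j, i in enumerate(idx):
            xs[i] = mx + block[j, 0]
            ys[i] = my + block[j, 1]
            zs[i] = mz + block[j, 2]

    out = pd.DataFrame({
        "burst_id": [f"b{i:07d}" for i in range(n)],
        "individual_id": sub["individual_id"].to_numpy(),
        "timestamp": sub["timestamp"].to_numpy(),
        "label": labels, "x": xs, "y": ys, "z": zs})
    for c in ("species", "sex"):
        if c in sub:
            out[c] = sub[c].to_numpy()
    return out


# -- direct response-scale simulators ---------------------------------

def _ar1_gamma(n: int, mu: np.ndarray, shape: float, rho: float, rng) -> np.ndarray:
    """Gamma marginals with AR1 dependence via a Gaussian copula.

    The latent series is stationary AR1; each value is mapped through
    the standard-normal CDF and the gamma quantile function, so the
    marginal mean is exactly ``mu`` while successive days correlate.
    """
    z = np.empty(n)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + np.sqrt(1 - rho ** 2) * eps[t]
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return stats.gamma.ppf(u, shape, scale=mu / shape)


def simulate_daily_distances(
    n_individuals: int = 20,
    n_days: int = 100,
    species_means: dict | None = None,
    p_disturbed: float = 0.2,
    p_in_field: float = 0.3,
    rho: float = 0.4,
    individual_sd: float = 0.12,
    gamma_shape: float = 16.0,
    exp_slopes: dict | None = None,
    n_farms: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Goose-day table with known gamma/log-scale truth for Eq-recovery.

    ``species_means`` maps species to (undisturbed_km, disturbed_km)
    marginal means; individual intercepts are lognormal with mean one so
    the population-averaged means equal the configured values exactly.
    ``exp_slopes`` optionally maps species to (undisturbed, disturbed)
    log-scale slopes on scaled cumulative experience, for testing the
    three-way interaction pattern.
    """
    species_means = species_means or {"GBG": (3.14, 4.32), "GWfG": (2.38, 2.57)}
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(2021, 11, 1)
    rows = []
    for sp in sorted(species_means):
        mu_u, mu_d = species_means[sp]
        for b in range(n_individuals):
            bird = f"{sp}{b + 1:02d}"
            sex = "M" if b % 2 == 0 else "F"
            bi = rng.normal(-individual_sd ** 2 / 2, individual_sd)
            disturbed = rng.random(n_days) < p_disturbed
            in_field = disturbed & (rng.random(n_days) < p_in_field)
            exp_raw = np.cumsum(disturbed)
            farm_pool = [f"F{rng.integers(n_farms) + 1:02d}" for _ in range(3)]
            mu = np.where(disturbed, mu_d, mu_u) * np.exp(bi)
            if exp_slopes and sp in exp_slopes:
                s_u, s_d = exp_slopes[sp]
                mu = mu * np.exp(np.where(disturbed, s_d, s_u) * exp_raw)
            td = _ar1_gamma(n_days, mu, gamma_shape, rho, rng)
            for t in range(n_days):
                rows.append((bird, sp, sex, winter_label(2021),
                             start + pd.Timedelta(days=t), t + 1,
                             farm_pool[rng.integers(3)], bool(disturbed[t]),
                             "in_field" if in_field[t] else
                             ("nearby" if disturbed[t] else "undisturbed"),
                             int(exp_raw[t]), td[t]))
    df = pd.DataFrame(rows, columns=[
        "individual_id", "species", "sex", "winter", "date", "date_index",
        "modal_farm_id", "disturbed", "disturbance_class", "exp_raw",
        "total_distance_km"])
    mu_sd = df["exp_raw"].std(ddof=0)
    df["exp_scaled"] = (df["exp_raw"] - df["exp_raw"].mean()) / (mu_sd if mu_sd > 0 else 1.0)
    df["n_fixes"] = 10
    return df


def simulate_budget_counts(
    n_individuals: int = 15,
    n_days: int = 60,
    baseline_logit: float = -0.2,
    shot_effect: float = 0.0,
    night_effect: float = -1.0,
    interaction: float = 0.0,
    theta: float = 25.0,
    mean_bursts: int = 30,
    p_disturbed: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Beta-binomial day/night behaviour counts with known logit truth."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(2021, 11, 1)
    rows = []
    for b in range(n_individuals):
        bird = f"GWfG{b + 1:02d}"
        disturbed = rng.random(n_days) < p_disturbed
        for t in range(n_days):
            for night in (False, True):
                n = max(6, rng.poisson(mean_bursts))
                lg = (baseline_logit + shot_effect * disturbed[t]
                      + night_effect * night + interaction * disturbed[t] * night)
                pi = 1.0 / (1.0 + np.exp(-lg))
                p = rng.beta(theta * pi, theta * (1 - pi))
                k = rng.binomial(n, p)
                rows.append((bird, winter_label(2021), start + pd.Timedelta(days=t),
                             t + 1, night, n, k, bool(disturbed[t])))
    return pd.DataFrame(rows, columns=[
        "individual_id", "winter", "date", "date_index", "is_night",
        "n_bursts", "k_bursts", "disturbed"])


def simulate_odba_days(
    n_individuals: int = 15,
    n_days: int = 100,
    intercept: float = 4.0,
    shot_effect: float = 0.0,
    bursts_coef: float = 0.01,
    date2_coef: float = 0.0,
    gamma_shape: float = 8.0,
    rho: float = 0.3,
    p_disturbed: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily total-ODBA table with known gamma log-link truth.

    ``date2_coef`` is the coefficient on the squared scaled date term
    (date centred mid-winter and scaled by 100 days), negative for a
    concave seasonal peak.
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(2021, 11, 1)
    rows = []
    for b in range(n_individuals):
        for sp in ("GBG", "GWfG"):
            bird = f"{sp}{b + 1:02d}"
            sex = "M" if b % 2 == 0 else "F"
            disturbed = rng.random(n_days) < p_disturbed
            nb = np.maximum(6, rng.poisson(40, n_days))
            t = np.arange(1, n_days + 1)
            ds = (t - 90) / 100.0
            mu = np.exp(intercept + shot_effect * disturbed + bursts_coef * nb
                        + date2_coef * ds ** 2)
            od = _ar1_gamma(n_days, mu, gamma_shape, rho, rng)
            for i in range(n_days):
                rows.append((bird, sp, sex, winter_label(2021),
                             start + pd.Timedelta(days=int(t[i]) - 1), int(t[i]),
                             od[i], int(nb[i]), bool(disturbed[i])))
    return pd.DataFrame(rows, columns=[
        "individual_id", "species", "sex", "winter", "date", "date_index",
        "total_odba", "n_bursts", "disturbed"])
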