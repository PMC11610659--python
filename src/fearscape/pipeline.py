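"""Configuration-driven orchestration of the full analysis.

simulate -> ingest -> displacement -> exposure -> daily movement ->
behaviour/ODBA -> habitat selection -> report.  Every stage logs row
counts in and out of each filter rule; outputs land in an output
directory as CSV/JSON/GeoJSON and a single ``report.json`` bundles the
headline quantities (coefficients, thresholds, rates, AIC tables,
evaluations).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from fearscape import accelerometry, displacement, exposure, habitat, io, movement
from fearscape.config import SimulationConfig
from fearscape.landscape import (
    generate_landscape,
    read_landscape_geojson,
    read_ascii_grid,
    write_ascii_grid,
    write_landscape_geojson,
)
from fearscape.simulate import (
    generate_acc_bursts,
    generate_shooting_log,
    generate_tracks,
    generate_training_bursts,
)

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def simulate_dataset(config: SimulationConfig, outdir: Path,
                     burst_every_nth_fix: int = 1) -> dict:
    """Generate and write the full synthetic dataset; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    land = generate_landscape(config)
    tracks = generate_tracks(land, config)
    events, tracks, truth = generate_shooting_log(land, tracks, config)
    bursts = generate_acc_bursts(tracks, config=config,
                                 every_nth_fix=burst_every_nth_fix)
    training = generate_training_bursts(config)

    paths = {
        "landscape": outdir / "landscape.geojson",
        "habitat": outdir / "habitat.asc",
        "tracks": outdir / "tracks.csv",
        "shooting_log": outdir / "shooting_log.csv",
        "bursts": outdir / "bursts.csv",
        "training_bursts": outdir / "training_bursts.csv",
        "displacement_truth": outdir / "displacement_truth.csv",
        "config": outdir / "simulation_config.yaml",
    }
    write_landscape_geojson(land, paths["landscape"])
    write_ascii_grid(land.habitat, land.cell_size, paths["habitat"])
    io.write_tracks(tracks, paths["tracks"])
    io.write_shooting_log(events, paths["shooting_log"])
    io.write_bursts(bursts, paths["bursts"])
    io.write_bursts(training, paths["training_bursts"])
    truth.to_csv(paths["displacement_truth"], index=False)
    config.to_yaml(paths["config"])
    logger.info("simulate: %d fixes, %d events, %d bursts written to %s",
                len(tracks), len(events), len(bursts), outdir)
    return {k: str(v) for k, v in paths.items()}


def load_dataset(paths: dict):
    land = read_landscape_geojson(paths["landscape"])
    if "habitat" in paths and Path(paths["habitat"]).exists():
        raster, cell, _, _ = read_ascii_grid(paths["habitat"])
        land.habitat = raster
        land.cell_size = cell
    tracks = io.read_tracks(paths["tracks"])
    events = io.read_shooting_log(paths["shooting_log"])
    bursts = io.read_bursts(paths["bursts"]) if "bursts" in paths else None
    training = (io.read_bursts(paths["training_bursts"])
                if "training_bursts" in paths else None)
    return land, tracks, events, bursts, training


def run_pipeline(
    config: SimulationConfig | None = None,
    paths: dict | None = None,
    outdir="fearscape_out",
    thresholds: str | dict = "published",
    burst_every_nth_fix: int = 1,
) -> dict:
    """Run every stage and write a report bundle.

    Exactly one of ``config`` (simulate block) or ``paths`` (existing
    dataset) must be given.  ``thresholds`` selects the exposure
    buffers: "published" (the reported per-species distances), "derived"
    (from this run's displacement fits) or an explicit mapping.
    """
    if (config is None) == (paths is None):
        raise ValueError("provide exactly one of config (simulate) or paths (ingest)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    if config is not None:
        paths = simulate_dataset(config, outdir / "data",
                                 burst_every_nth_fix=burst_every_nth_fix)
    land, tracks, events, bursts, training = load_dataset(paths)

    # -- ingest: resample + annotate
    n_raw = len(tracks)
    fixes = io.annotate_fixes(io.resample_hourly(tracks), land)
    logger.info("resample_hourly: %d -> %d fixes", n_raw, len(fixes))
    report["ingest"] = {"n_raw_fixes": n_raw, "n_hourly_fixes": len(fixes),
                        "n_events": len(events)}

    # -- displacement (Prediction 1)
    pairs = displacement.build_step_pairs(fixes, events)
    fits = {}
    for sp, mode in (("GBG", "fixed"), ("GWfG", "random")):
        sub = pairs[pairs["species"] == sp]
        if len(sub) >= 30 and sub["individual_id"].nunique() >= 2:
            fits[sp] = displacement.fit_displacement_model(pairs, species=sp,
                                                           winter_mode=mode)
    thr_report = displacement.threshold_report(fits)
    report["displacement"] = {"n_pairs": len(pairs), "per_species": thr_report}
    if fits:
        pd.concat([f.to_frame() for f in fits.values()]).to_csv(
            outdir / "displacement_coefficients.csv", index=False)
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(_jsonable(thr_report), fh, indent=2)

    # -- exposure (Prediction 2)
    if thresholds == "published":
        buffers = dict(exposure.DEFAULT_BUFFERS_M)
    elif thresholds == "derived":
        buffers = {sp: (thr_report[sp]["threshold_m"]
                        or exposure.DEFAULT_BUFFERS_M[sp]) for sp in fits}
        for sp in exposure.DEFAULT_BUFFERS_M:
            buffers.setdefault(sp, exposure.DEFAULT_BUFFERS_M[sp])
    else:
        buffers = dict(thresholds)
    records = exposure.classify_exposure(fixes, events, buffers, land.fields)
    records = exposure.cumulative_experience(records)
    rates, rate_summary = exposure.disturbance_rate(records)
    records.to_csv(outdir / "exposure_records.csv", index=False)
    rates.to_csv(outdir / "disturbance_rates.csv", index=False)
    report["exposure"] = {
        "buffers_m": buffers,
        "n_goose_days": len(records),
        "n_disturbed_days": int(records["disturbed"].sum()),
        "rates": rate_summary.set_index("species").to_dict("index")}

    # -- daily movement (Prediction 3)
    summaries = movement.daily_distance(fixes)
    n_all_days = fixes[fixes["is_day"]].groupby(
        ["individual_id", fixes["timestamp"].dt.normalize()]).ngroups
    logger.info("daily_distance: %d goose-days, %d dropped by the 8-fix rule",
                len(summaries), n_all_days - len(summaries))
    summaries = movement.merge_exposure(summaries, records)
    report["movement"] = {"n_goose_days": len(summaries),
                          "n_dropped_lt8_fixes": n_all_days - len(summaries)}
    if summaries["species"].nunique() == 2 and len(summaries) > 50:
        comp, mfits = movement.run_model_set(summaries)
        comp.to_csv(outdir / "distance_model_comparison.csv", index=False)
        best_name = comp.iloc[0]["model"]
        gfit = movement.fit_distance_model(summaries, formula=comp.iloc[0]["formula"])
        mm = pd.concat([movement.marginal_means(gfit, sp)
                        for sp in ("GBG", "GWfG")], ignore_index=True) \
            if "shot2" in comp.iloc[0]["formula"] or "disturbance_class" in comp.iloc[0]["formula"] \
            else None
        report["movement"].update({
            "best_model": best_name,
            "ar1_rho": gfit.rho,
            "marginal_means_km": (mm.to_dict("records") if mm is not None else None)})
        if mm is not None:
            mm.to_csv(outdir / "distance_marginal_means.csv", index=False)

    # -- behaviour + ODBA (Predictions 4-5)
    if training is not None and len(training):
        clf = accelerometry.train_behavior_classifier(training, seed=config.seed if config else 0)
        report["behavior_classifier"] = {
            "accuracy": clf.accuracy, "ci": list(clf.accuracy_ci),
            "n_train": clf.n_train, "n_test": clf.n_test}
        clf.confusion.to_csv(outdir / "classifier_confusion.csv")
        if bursts is not None and len(bursts):
            classified = clf.predict(bursts)
            budgets = accelerometry.build_budgets(classified, records)
            budgets.to_csv(outdir / "activity_budgets.csv", index=False)
            report["budgets"] = {"n_day_nights": len(budgets)}
            for beh in ("grazing", "stationary", "flying"):
                if budgets[f"bursts_{beh}"].sum() == 0:
                    continue
                comp_b, bfits = accelerometry.fit_budget_model(budgets, beh)
                comp_b.to_csv(outdir / f"budget_models_{beh}.csv", index=False)
                report["budgets"][beh] = {
                    "best_model": comp_b.iloc[0]["model"],
                    "aic_table": comp_b[["model", "k", "AIC", "dAIC"]].to_dict("records")}
            classified["odba"] = [accelerometry.compute_odba(r)
                                  for r in classified[["x", "y", "z"]].to_dict("records")]
            odba_daily = accelerometry.build_odba_daily(classified, records)
            odba_daily.to_csv(outdir / "odba_daily.csv", index=False)
            if len(odba_daily) > 50:
                comp_o, ofits = accelerometry.fit_odba_model(odba_daily)
                comp_o.to_csv(outdir / "odba_model_comparison.csv", index=False)
                report["odba"] = {
                    "n_goose_days": len(odba_daily),
                    "best_model": comp_o.iloc[0]["model"],
                    "aic_table": comp_o[["model", "k", "AIC", "dAIC"]].to_dict("records")}

    # -- habitat selection (Prediction 6)
    rsf_report = {}
    day_fixes = fixes[fixes["is_day"]].copy()
    day_fixes["date"] = day_fixes["timestamp"].dt.normalize()
    rec_idx = records.set_index(["individual_id", "date"])
    seed = config.seed if config else 0
    first_ev = exposure.first_exposure_times(day_fixes, events, buffers)
    for sp in sorted(day_fixes["species"].unique()):
        sp_fix = day_fixes[day_fixes["species"] == sp]
        if len(sp_fix) < 100:
            continue
        mcp = habitat.species_mcp(sp_fix)
        from shapely.geometry import mapping as _mapping

        with open(outdir / f"mcp_{sp}.geojson", "w") as fh:
            json.dump({"type": "Feature", "properties": {"species": sp},
                       "geometry": _mapping(mcp)}, fh)
        used = sp_fix[["individual_id", "x", "y", "timestamp", "date"]].copy()
        pts = habitat.build_rsf_points(used, mcp, seed=seed)
        pts = habitat.annotate_rsf_points(pts, land)
        key = pd.MultiIndex.from_arrays([pts["individual_id"], pts["date"]])
        disturbed = rec_idx["disturbed"].reindex(key).to_numpy()
        pts["shooting_day"] = np.where(
            pts["used"] == 1, np.where(disturbed == True, "shooting", "none"),  # noqa: E712
            "none")
        # pseudoabsences are availability: replicate across classes
        between = fit = None
        try:
            between = habitat.fit_rsf(pts, design="between_days")
            rsf_report[sp] = {"between_days": {
                "aic": between.aic, **between.evaluation.to_dict()}}
            between.to_frame().to_csv(outdir / f"rsf_between_{sp}.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            rsf_report[sp] = {"between_days": {"failed": str(exc)}}

        # within-day: disturbed days only, pre/post the first exposing event
        w = pts[pts["used"] == 1].merge(first_ev, on=["individual_id", "date"],
                                        how="inner")
        if len(w) >= 100:
            w["period"] = np.where(w["timestamp"] <= w["first_event_timestamp"],
                                   "pre", "post")
            # availability at the design ratio for this (smaller) table:
            # a seeded 10:1 subsample of the species pool, split over periods
            pa = (pts[pts["used"] == 0]
                  .sample(n=min(10 * len(w), int((pts["used"] == 0).sum())),
                          random_state=seed)
                  .reset_index(drop=True))
            pa["period"] = np.where(np.arange(len(pa)) % 2 == 0, "pre", "post")
            wtab = pd.concat([w, pa], ignore_index=True)
            wtab = habitat.group_rare_habitats(wtab)
            try:
                within = habitat.fit_rsf(wtab, design="within_days")
                rsf_report[sp]["within_days"] = {
                    "aic": within.aic, **within.evaluation.to_dict(),
                    "habitats": sorted(wtab["habitat"].unique())}
                within.to_frame().to_csv(outdir / f"rsf_within_{sp}.csv", index=False)
            except Exception as exc:  # noqa: BLE001
                rsf_report[sp]["within_days"] = {"failed": str(exc)}
    report["habitat_selection"] = rsf_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, default=str)
    logger.info("pipeline complete: report at %s", outdir / "report.json")
    return report


def make_fixtures(seed: int = 0, outdir="fixtures") -> dict:
    """Small bundled dataset exercising every filter rule.

    Two species x 5 birds x ~1 month at hourly fixes; daily shooting so
    in-field and nearby exposures, sub-8-fix days and sub-6-burst
    nights all occur.  Total size well under 1 MB of delimited text.
    """
    cfg = SimulationConfig(
        seed=seed, n_individuals_per_species=5, n_winters=1,
        start_month_day=(11, 1), end_month_day=(11, 30),
        first_winter_year=2021, shooting_rate=1.5,
        cell_size_m=50.0, burst_n_samples=6,
        behavior_counts={"walking": 40, "grazing": 160, "alert": 50,
                         "resting": 30, "flying": 170})
    paths = simulate_dataset(cfg, Path(outdir), burst_every_nth_fix=1)
    # a day with fewer than 8 fixes for one bird (tag outage analogue)
    tracks = io.read_tracks(paths["tracks"])
    bird = tracks["individual_id"].iloc[0]
    day = tracks["timestamp"].dt.normalize() == pd.Timestamp(2021, 11, 10)
    mask = (tracks["individual_id"] == bird) & day
    keep = tracks[~mask | (tracks["timestamp"].dt.hour < 5)].copy()
    keep[["x", "y"]] = keep[["x", "y"]].round(1)
    io.write_tracks(keep, paths["tracks"])
    # bursts: thin nights to every other fix (still >= 6 per night), then
    # leave one night with only five bursts for the same bird
    bursts = io.read_bursts(paths["bursts"])
    from fearscape import solar as _solar

    night = ~_solar.is_daytime(bursts["timestamp"])
    thin = night & (bursts["timestamp"].dt.hour % 2 == 1)
    bursts = bursts[~thin]
    night = ~_solar.is_daytime(bursts["timestamp"])
    nmask = ((bursts["individual_id"] == bird) & night
             & (bursts["timestamp"].dt.normalize() == pd.Timestamp(2021, 11, 15)))
    drop = bursts.index[nmask][5:]
    io.write_bursts(bursts.drop(index=drop), paths["bursts"], precision=3)
    training = io.read_bursts(paths["training_bursts"])
    io.write_bursts(training, paths["training_bursts"], precision=3)
    return paths
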