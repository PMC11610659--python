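"""Daily foraging distance and its response to shooting disturbance.

Total daily distance (TD, km) is the cumulative point-to-point distance
over a goose-day's daytime fixes; days with fewer than eight fixes are
dropped.  TD is modelled with a gamma log-link model whose global form
crosses shooting disturbance (2- or 3-level), species and scaled
cumulative shooting experience, with sex as a control, an AR1 structure
over each individual-winter day series and the modal farm recorded for
each day (the farm holding most of the day's fixes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fearscape.ar1glm import GammaAR1Fit, compare_models, fit_gamma_ar1

MIN_FIXES_PER_DAY = 8

SHOT2 = "C(shot2, Treatment('undisturbed'))"
SHOT3 = "C(disturbance_class, Treatment('undisturbed'))"


def daily_distance(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per goose-day summaries from annotated hourly fixes.

    Daytime fixes only; TD in km; modal farm with lexicographic
    tie-break (NA when every fix is outside farms).
    """
    day = fixes[fixes["is_day"]].sort_values(["individual_id", "timestamp"])
    if day.empty:
        return pd.DataFrame(columns=[
            "individual_id", "species", "sex", "winter", "date", "date_index",
            "n_fixes", "total_distance_km", "modal_farm_id"])
    day = day.copy()
    day["date"] = day["timestamp"].dt.normalize()

    def _one(grp: pd.DataFrame):
        xy = grp[["x", "y"]].to_numpy(float)
        td = float(np.sum(np.hypot(*np.diff(xy, axis=0).T))) / 1000.0
        farms = grp["farm_id"].dropna()
        modal = None
        if len(farms):
            counts = farms.value_counts()
            top = counts[counts == counts.max()].index
            modal = sorted(top)[0]
        return pd.Series({
            "species": grp["species"].iloc[0], "sex": grp["sex"].iloc[0],
            "winter": grp["winter"].iloc[0],
            "date_index": int(grp["date_index"].iloc[0]),
            "n_fixes": len(grp), "total_distance_km": td,
            "modal_farm_id": modal})

    out = (day.groupby(["individual_id", "date"])
              .apply(_one, include_groups=False).reset_index())
    kept = out[out["n_fixes"] >= MIN_FIXES_PER_DAY].reset_index(drop=True)
    return kept


def merge_exposure(summaries: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Attach disturbance class and scaled experience to goose-days."""
    cols = ["individual_id", "date", "disturbed", "disturbance_class",
            "exp_raw", "exp_scaled"]
    cols = [c for c in cols if c in records.columns]
    out = summaries.merge(records[cols], on=["individual_id", "date"], how="left")
    out["disturbed"] = out["disturbed"].fillna(False)
    out["disturbance_class"] = out["disturbance_class"].fillna("undisturbed")
    for c in ("exp_raw", "exp_scaled"):
        if c in out:
            out[c] = out[c].fillna(0.0)
    return out


def _prep(summaries: pd.DataFrame) -> pd.DataFrame:
    df = summaries.copy()
    if "disturbed" not in df and "disturbance_class" in df:
        df["disturbed"] = df["disturbance_class"] != "undisturbed"
    df["shot2"] = np.where(df["disturbed"], "disturbed", "undisturbed")
    df["ind_winter"] = df["individual_id"].astype(str) + ":" + df["winter"].astype(str)
    if "exp_scaled" not in df:
        df["exp_scaled"] = 0.0
    return df


def global_formula(shot_levels: int = 2) -> str:
    shot = SHOT2 if shot_levels == 2 else SHOT3
    return f"total_distance_km ~ {shot} * species * exp_scaled + sex"


def fit_distance_model(
    summaries: pd.DataFrame,
    formula: str | None = None,
    shot_levels: int = 2,
    use_gee: bool = True,
) -> GammaAR1Fit:
    """Fit one daily-distance model (gamma log link, AR1 day series)."""
    df = _prep(summaries)
    if "species" in (formula or global_formula(shot_levels)) and df["species"].nunique() < 2:
        raise ValueError("species term requires >= 2 species levels")
    return fit_gamma_ar1(df, formula or global_formula(shot_levels),
                         group_col="ind_winter", time_col="date_index",
                         use_gee=use_gee)


def marginal_means(
    fit: GammaAR1Fit,
    species: str,
    shot_levels: int = 2,
    sex: str = "F",
) -> pd.DataFrame:
    """Back-transformed mean TD (km) per disturbance level.

    Computed at scaled experience 0 (the mean of the scaled variable)
    and the stated reference sex.
    """
    levels = (["undisturbed", "disturbed"] if shot_levels == 2
              else ["undisturbed", "in_field", "nearby"])
    col = "shot2" if shot_levels == 2 else "disturbance_class"
    newdata = pd.DataFrame({
        col: levels, "species": species, "exp_scaled": 0.0, "sex": sex})
    if col == "shot2":
        newdata["disturbance_class"] = "undisturbed"
    else:
        newdata["shot2"] = "undisturbed"
    pred = fit.predict_mean(newdata)
    pred.insert(0, "level", levels)
    pred.insert(0, "species", species)
    return pred


def default_model_set() -> dict:
    """A priori daily-distance model set.

    Global three-way models for both codings of the disturbance factor,
    then progressively simpler interaction structures, down to a
    species+sex null.  Species and sex appear in every model.
    """
    sets = {}
    for tag, shot in (("shot2", SHOT2), ("shot3", SHOT3)):
        sets[f"global_3way_{tag}"] = (
            f"total_distance_km ~ {shot} * species * exp_scaled + sex")
        sets[f"all_2way_{tag}"] = (
            f"total_distance_km ~ ({shot} + species + exp_scaled)**2 + sex")
        sets[f"shotXsp_spXexp_{tag}"] = (
            f"total_distance_km ~ {shot} * species + species * exp_scaled + sex")
        sets[f"shotXsp_shotXexp_{tag}"] = (
            f"total_distance_km ~ {shot} * species + {shot} * exp_scaled + sex")
        sets[f"shotXsp_{tag}"] = (
            f"total_distance_km ~ {shot} * species + exp_scaled + sex")
        sets[f"additive_{tag}"] = (
            f"total_distance_km ~ {shot} + species + exp_scaled + sex")
        sets[f"shot_only_{tag}"] = (
            f"total_distance_km ~ {shot} + species + sex")
    sets["exp_only"] = "total_distance_km ~ exp_scaled + species + sex"
    sets["null"] = "total_distance_km ~ species + sex"
    return sets


def run_model_set(
    summaries: pd.DataFrame,
    model_set: dict | None = None,
    use_gee: bool = False,
) -> tuple:
    """Fit the a priori model set on identical rows; rank by AIC.

    Returns ``(comparison, fits)``; the comparison table carries k, AIC
    and dAIC (0 for the lowest-AIC model).  Non-converging models are
    recorded as failed and excluded from the ranking.
    """
    df = _prep(summaries)
    return compare_models(df, model_set or default_model_set(),
                          group_col="ind_winter", time_col="date_index",
                          use_gee=use_gee)
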