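"""Displacement decay around shooting events.

Birds act as their own controls: for each shooting event the GPS fix
immediately prior is retained if it is within 1 h and 4 km of the event
field centroid, and the difference between the exposed step length
(SL_t) and the preceding control step (SL_{t-1}) is modelled against
the natural log of distance to the event with a linear mixed model:

    dSL = a + b1*ln(Dist) + b2*Time + b3*Time^2 [+ b4*Winter] + e_i

with a random intercept per individual; for species with many tracked
winters the winter term moves from a fixed effect to a crossed random
intercept.  The species-specific disturbance distance is the smallest
distance at which the lower 95% CI of the fitted decay curve reaches
zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

MAX_PAIR_DIST_M = 4000.0
MAX_PAIR_AGE_H = 1.0


def build_step_pairs(
    fixes: pd.DataFrame,
    events: pd.DataFrame,
    max_dist_m: float = MAX_PAIR_DIST_M,
    max_age_h: float = MAX_PAIR_AGE_H,
) -> pd.DataFrame:
    """Paired exposed/control steps around shooting events.

    ``fixes`` must be hourly-resampled and annotated (winter, species).
    One row per (bird, event) where the pre-event fix is within
    ``max_age_h`` hours and ``max_dist_m`` metres of the event centroid
    and three consecutive fixes exist; when several events are eligible
    for the same step, only the nearest is kept.  Ineligible
    combinations are counted in the log.
    """
    cols = ["individual_id", "event_id", "species", "winter", "SL_t", "SL_t_minus_1",
            "delta_SL", "dist_to_event", "event_time_h"]
    if fixes.empty or events.empty:
        return pd.DataFrame(columns=cols)

    rows = []
    n_skipped = 0
    ev_ts = events["timestamp"].to_numpy()
    ev_xy = events[["centroid_x", "centroid_y"]].to_numpy(float)
    ev_id = events["event_id"].to_numpy()
    ev_hours = (events["timestamp"] - events["timestamp"].dt.normalize()
                ).dt.total_seconds().to_numpy() / 3600.0

    for bird, grp in fixes.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp")
        ts = grp["timestamp"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(float)
        species = grp["species"].iloc[0]
        winters = grp["winter"].to_numpy()
        idx = np.searchsorted(ts, ev_ts, side="right") - 1
        for e in range(len(events)):
            i = idx[e]
            if i < 1 or i + 1 >= len(ts):
                n_skipped += 1
                continue
            age_h = (ev_ts[e] - ts[i]) / np.timedelta64(1, "h")
            if age_h > max_age_h or age_h < 0:
                n_skipped += 1
                continue
            dist = float(np.hypot(*(xy[i] - ev_xy[e])))
            if dist > max_dist_m:
                n_skipped += 1
                continue
            sl_t = float(np.hypot(*(xy[i + 1] - xy[i])))
            sl_tm1 = float(np.hypot(*(xy[i] - xy[i - 1])))
            rows.append((bird, ev_id[e], species, winters[i], sl_t, sl_tm1,
                         sl_t - sl_tm1, dist, float(ev_hours[e]), i))

    if not rows:
        logger.info("build_step_pairs: 0 pairs retained, %d excluded", n_skipped)
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=cols + ["_fix_i"])
    # one response row per exposed step: keep the nearest event
    df = (df.sort_values(["individual_id", "_fix_i", "dist_to_event"])
            .groupby(["individual_id", "_fix_i"], as_index=False).head(1)
            .drop(columns="_fix_i")
            .reset_index(drop=True))
    logger.info("build_step_pairs: %d pairs retained, %d (bird,event) excluded",
                len(df), n_skipped)
    return df


@dataclass
class DisplacementFit:
    """Fitted displacement-decay model for one species."""

    species: str
    params: pd.Series            # fixed effects
    cov: pd.DataFrame            # fixed-effect covariance
    n_pairs: int
    n_individuals: int
    winter_mode: str             # "fixed" | "random" | "none"
    ref_time_h: float            # event time at which predictions are made
    random_variances: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def intercept(self) -> float:
        return float(self.params["Intercept"])

    @property
    def slope_logdist(self) -> float:
        return float(self.params["log_dist"])

    def _xrow(self, dist_m: np.ndarray) -> np.ndarray:
        """Design rows at reference covariates (mean event time, ref winter)."""
        d = np.atleast_1d(np.asarray(dist_m, float))
        x = np.zeros((d.size, len(self.params)))
        names = list(self.params.index)
        x[:, names.index("Intercept")] = 1.0
        x[:, names.index("log_dist")] = np.log(np.maximum(d, 1.0))
        if "time_h" in names:
            x[:, names.index("time_h")] = self.ref_time_h
        if "time_h2" in names:
            x[:, names.index("time_h2")] = self.ref_time_h ** 2
        return x

    def predict(self, dist_m, ci: bool = True):
        """Mean predicted dSL at distance(s), with fixed-effect 95% CI."""
        x = self._xrow(dist_m)
        mean = x @ self.params.to_numpy()
        if not ci:
            return mean
        se = np.sqrt(np.einsum("ij,jk,ik->i", x, self.cov.to_numpy(), x))
        return mean, mean - 1.96 * se, mean + 1.96 * se

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table."""
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.DataFrame({
            "species": self.species, "term": self.params.index,
            "estimate": self.params.to_numpy(), "se": se,
            "ci_lo": self.params.to_numpy() - 1.96 * se,
            "ci_hi": self.params.to_numpy() + 1.96 * se})


def _check_collinear(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the last column whose removal restores full rank
        for j in range(arr.shape[1] - 1, -1, -1):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(
                    f"singular design: term '{X.columns[j]}' is collinear")
        raise ValueError("singular design matrix")


def fit_displacement_model(
    pairs: pd.DataFrame,
    species: str | None = None,
    winter_mode: str = "fixed",
    min_pairs: int = 30,
) -> DisplacementFit:
    """Fit the per-species displacement-decay mixed model.

    ``winter_mode`` is "fixed" (winter as a fixed factor — used when
    only two winters are tracked), "random" (crossed random intercept
    alongside individual) or "none" (single-winter data).  Natural log
    of distance; distances are floored at 1 m before the log.
    """
    df = pairs if species is None else pairs[pairs["species"] == species]
    df = df.copy()
    if len(df) < min_pairs:
        raise ValueError(f"need >= {min_pairs} step pairs, have {len(df)}")
    if df["individual_id"].nunique() < 2:
        raise ValueError("need step pairs from >= 2 individuals")
    sp = species or (df["species"].iloc[0] if "species" in df else "all")

    df["log_dist"] = np.log(np.maximum(df["dist_to_event"].astype(float), 1.0))
    df["time_h"] = df["event_time_h"].astype(float)
    df["time_h2"] = df["time_h"] ** 2

    rhs = "log_dist + time_h + time_h2"
    n_winters = df["winter"].nunique() if "winter" in df else 1
    if winter_mode == "fixed" and n_winters > 1:
        rhs += " + C(winter)"

    from patsy import dmatrix

    _check_collinear(pd.DataFrame(
        np.asarray(dmatrix(rhs, df)),
        columns=dmatrix(rhs, df).design_info.column_names))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if winter_mode == "random" and n_winters > 1:
            df["_one"] = 1
            model = smf.mixedlm(
                f"delta_SL ~ {rhs}", df, groups="_one", re_formula="0",
                vc_formula={"individual": "0 + C(individual_id)",
                            "winter": "0 + C(winter)"})
        else:
            model = smf.mixedlm(f"delta_SL ~ {rhs}", df, groups="individual_id")
        se_cap = 1e3 * max(float(df["delta_SL"].std()), 1.0)
        res = None
        for method in (None, "lbfgs", "cg", "powell"):
            try:
                cand = (model.fit(reml=True) if method is None
                        else model.fit(reml=True, method=method))
            except Exception:
                continue
            d = np.diag(cand.cov_params())[: len(cand.fe_params)]
            se_ok = (np.all(np.isfinite(d)) and np.all(d > 0)
                     and np.sqrt(d.max()) < se_cap)
            if cand.converged and se_ok:
                res = cand
                break
            if res is None and se_ok:
                res = cand

    if res is not None:
        fe = res.fe_params
        cov = res.cov_params().loc[fe.index, fe.index]
        rvar = {}
        if hasattr(res, "vcomp") and res.vcomp is not None and len(res.vcomp):
            for name, v in zip(model.exog_vc.names, np.atleast_1d(res.vcomp)):
                rvar[name] = float(v)
        else:
            rvar["individual"] = (float(np.asarray(res.cov_re).ravel()[0])
                                  if res.cov_re.size else 0.0)
        converged = bool(res.converged)
    else:
        # mixed-model optimizer defeated: individual-clustered OLS keeps
        # the fixed-effect estimates and honest (robust) uncertainty
        ols = smf.ols(f"delta_SL ~ {rhs}", df).fit(
            cov_type="cluster", cov_kwds={"groups": df["individual_id"]})
        fe = ols.params
        cov = ols.cov_params()
        rvar = {}
        converged = False

    return DisplacementFit(
        species=sp, params=fe, cov=cov, n_pairs=len(df),
        n_individuals=df["individual_id"].nunique(),
        winter_mode=winter_mode if n_winters > 1 else "none",
        ref_time_h=float(df["time_h"].mean()),
        random_variances=rvar, converged=converged)


def derive_disturbance_threshold(
    fit: DisplacementFit,
    grid_max_m: float = 4000.0,
    grid_step_m: float = 10.0,
    grid_min_m: float = 1.0,
) -> float:
    """Distance at which displacement stops being detectable.

    Smallest distance where the lower 95% CI of the predicted decay
    curve (at mean event time, reference winter, fixed-effect
    uncertainty only) reaches zero; refined by bisection to well under
    1 m.  Returns ``inf`` if no crossing exists on the grid (lower CI
    positive throughout, or a non-negative distance slope).
    """
    if fit.slope_logdist >= 0:
        return float("inf")

    def lower(d):
        _, lo, _ = fit.predict(d)
        return float(lo[0])

    grid = np.arange(grid_min_m, grid_max_m + grid_step_m, grid_step_m)
    prev = grid[0]
    if lower(prev) <= 0:
        return float(prev)
    for d in grid[1:]:
        if lower(d) <= 0:
            lo_d, hi_d = prev, d
            while hi_d - lo_d > 0.01:
                mid = 0.5 * (lo_d + hi_d)
                if lower(mid) <= 0:
                    hi_d = mid
                else:
                    lo_d = mid
            return 0.5 * (lo_d + hi_d)
        prev = d
    return float("inf")


def threshold_report(fits: dict, **kwargs) -> dict:
    """Per-species disturbance-distance report (JSON-ready)."""
    report = {}
    for sp, f in fits.items():
        thr = derive_disturbance_threshold(f, **kwargs)
        report[sp] = {
            "threshold_m": thr if np.isfinite(thr) else None,
            "no_crossing_below_grid_max": not np.isfinite(thr),
            "intercept": f.intercept,
            "slope_logdist": f.slope_logdist,
            "n_pairs": f.n_pairs,
        }
    return report
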