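"""Resource selection: used fixes versus pseudoabsences.

Availability is the 100% minimum convex polygon of a species' daytime
fixes; pseudoabsences are sampled uniformly inside it at 10 per used
fix.  Weighted logistic regression (used = 1 weight 10, pseudoabsence
= 0 weight 1) contrasts habitat use between shooting-disturbed and
undisturbed days, and — within disturbed days — before and after the
first shooting event with distance to road in a three-way interaction.
No random intercepts: the used:pseudoabsence ratio is constant by
design.  Fit quality is summarised by ROC/AUC and confusion metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
import statsmodels.formula.api as smf
from shapely.geometry import MultiPoint
from shapely.ops import unary_union
from sklearn.metrics import roc_auc_score

from fearscape.config import HABITAT_CLASSES
from fearscape.landscape import Landscape

MIN_USED_FIXES_PER_HABITAT = 50


def species_mcp(fixes: pd.DataFrame):
    """100% minimum convex polygon over a species' fixes.

    Raises for fewer than three distinct points or collinear input
    (degenerate hull).
    """
    pts = fixes[["x", "y"]].drop_duplicates().to_numpy(float)
    if len(pts) < 3:
        raise ValueError("need >= 3 distinct fixes for an MCP")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise ValueError("degenerate hull: fixes are collinear")
    return hull


def sample_pseudoabsences(mcp, n_used: int, ratio: int = 10, seed: int = 0) -> pd.DataFrame:
    """Exactly ``ratio * n_used`` uniform points inside the polygon.

    Rejection sampling from the bounding box; reproducible under seed.
    """
    rng = np.random.default_rng(seed)
    n_target = ratio * n_used
    minx, miny, maxx, maxy = mcp.bounds
    xs, ys = [], []
    got = 0
    while got < n_target:
        m = max(1000, int((n_target - got) * 2.5))
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        inside = shapely.contains_xy(mcp, cx, cy)
        take = min(int(inside.sum()), n_target - got)
        idx = np.nonzero(inside)[0][:take]
        xs.append(cx[idx])
        ys.append(cy[idx])
        got += take
    return pd.DataFrame({"x": np.concatenate(xs), "y": np.concatenate(ys)})


def build_rsf_points(
    used: pd.DataFrame,
    mcp,
    ratio: int = 10,
    seed: int = 0,
    used_weight: float = 10.0,
) -> pd.DataFrame:
    """Stack used fixes and freshly sampled pseudoabsences.

    Pseudoabsences are generated once per species table and shared
    across disturbance classes; classification variables on them are
    assigned by replication at model-build time.
    """
    u = used.copy()
    u["used"] = 1
    u["weight"] = used_weight
    pa = sample_pseudoabsences(mcp, len(used), ratio=ratio, seed=seed)
    pa["used"] = 0
    pa["weight"] = 1.0
    return pd.concat([u, pa], ignore_index=True)


def annotate_rsf_points(
    points: pd.DataFrame,
    landscape: Landscape,
    scale_road: bool = True,
) -> pd.DataFrame:
    """Habitat class (raster lookup) and scaled distance to road.

    Off-raster points are dropped with a warning.  Road distance is
    z-scored over the supplied table (used + pseudoabsence rows of the
    model being fitted) when ``scale_road``.
    """
    out = points.copy()
    code = landscape.habitat_at(out["x"].to_numpy(), out["y"].to_numpy())
    keep = code >= 0
    if not keep.all():
        import warnings

        warnings.warn(f"{(~keep).sum()} points off the habitat raster; dropped")
        out = out[keep].reset_index(drop=True)
        code = code[keep]
    out["habitat"] = [HABITAT_CLASSES[int(c)] for c in code]
    roads = unary_union(landscape.roads)
    pts = shapely.points(out["x"].to_numpy(), out["y"].to_numpy())
    d = shapely.distance(pts, roads)
    out["dist_road_m"] = d
    if scale_road:
        sd = d.std()
        out["dist_road_scaled"] = (d - d.mean()) / (sd if sd > 0 else 1.0)
    return out


def group_rare_habitats(
    points: pd.DataFrame,
    period_col: str = "period",
    min_used: int = MIN_USED_FIXES_PER_HABITAT,
) -> pd.DataFrame:
    """Collapse habitats rare among used fixes to "other".

    A habitat is kept only if it has at least ``min_used`` used fixes
    in the pre- or the post-shooting class; habitats below the cutoff
    in *both* classes are relabelled "other".
    """
    used = points[points["used"] == 1]
    counts = (used.groupby(["habitat", period_col]).size().unstack(fill_value=0))
    keep = counts.index[(counts >= min_used).any(axis=1)]
    out = points.copy()
    out["habitat"] = np.where(out["habitat"].isin(keep), out["habitat"], "other")
    return out


@dataclass
class RsfEvaluation:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    predictive_power: float
    confusion: dict

    def to_dict(self) -> dict:
        return {"auc": self.auc, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "accuracy": self.accuracy,
                "predictive_power": self.predictive_power, **self.confusion}


@dataclass
class RsfFit:
    design: str
    formula: str
    params: pd.Series
    cov: pd.DataFrame
    aic: float
    evaluation: RsfEvaluation
    result: object

    def to_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.DataFrame({
            "term": self.params.index, "estimate": self.params.to_numpy(),
            "se": se, "ci_lo": self.params.to_numpy() - 1.96 * se,
            "ci_hi": self.params.to_numpy() + 1.96 * se})


def _evaluate(y, score, threshold: float = 0.5) -> RsfEvaluation:
    y = np.asarray(y)
    score = np.asarray(score)
    pred = (score >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return RsfEvaluation(
        auc=float(roc_auc_score(y, score)), sensitivity=sens, specificity=spec,
        accuracy=acc, predictive_power=ppv,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn})


def fit_rsf(points: pd.DataFrame, design: str = "between_days",
            threshold: float = 0.5) -> RsfFit:
    """Weighted binomial RSF for one species table.

    ``design="between_days"``: habitat x shooting-day two-way
    interaction.  ``design="within_days"``: habitat x period (pre/post
    first event) x scaled road distance three-way interaction, on the
    grouped habitat classes.  Separation (a habitat level with no
    pseudoabsences) raises a warning but the fit proceeds.
    """
    df = points.copy()
    if df["used"].nunique() < 2:
        raise ValueError("need both used and pseudoabsence rows")
    if design == "between_days":
        formula = "used ~ C(habitat) * C(shooting_day)"
    elif design == "within_days":
        formula = "used ~ C(habitat) * C(period) * dist_road_scaled"
    else:
        raise ValueError(f"unknown design '{design}'")

    # separation diagnostic
    pa_per_hab = df[df["used"] == 0].groupby("habitat").size()
    empty = set(df["habitat"].unique()) - set(pa_per_hab.index)
    if empty:
        import warnings

        warnings.warn(f"habitat level(s) with no pseudoabsences: {sorted(empty)}")

    model = smf.glm(formula, df, family=sm.families.Binomial(),
                    freq_weights=df["weight"].to_numpy())
    res = model.fit()
    score = res.predict(df)
    ev = _evaluate(df["used"], score, threshold=threshold)
    return RsfFit(design=design, formula=formula, params=res.params,
                  cov=res.cov_params(), aic=float(res.aic), evaluation=ev,
                  result=res)


def relative_use(fit: RsfFit, newdata: pd.DataFrame) -> np.ndarray:
    """Predicted relative probability of use (0.5 = use matches availability)."""
    return np.asarray(fit.result.predict(newdata))
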