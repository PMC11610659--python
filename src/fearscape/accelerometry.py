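"""Accelerometer-derived behaviour and energy expenditure.

Overall dynamic body acceleration (ODBA) for a burst of n tri-axial
samples is the summed per-axis mean absolute deviation:

    ODBA = sum_i (|x_i - xbar| + |y_i - ybar| + |z_i - zbar|) / n

a standard proxy for energy expenditure.  Bursts are classified into
five behaviours with a random forest over summary features, collapsed
to four analysis behaviours (walking, grazing, stationary = alert +
resting, flying).  Day/night activity budgets are modelled with a
beta-binomial regression (logit link, dispersion parameterised as
a = theta*pi, b = theta*(1-pi)); daily summed ODBA with a gamma
log-link model with AR1 day series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln, logit
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from statsmodels.base.model import GenericLikelihoodModel
from statsmodels.stats.proportion import proportion_confint
import patsy

from fearscape import solar
from fearscape.ar1glm import GammaAR1Fit, compare_models, fit_gamma_ar1
from fearscape.io import date_index_of, winter_of

MIN_BURSTS_PER_PERIOD = 6
MIN_DAYS_PER_WINTER = 10

COLLAPSE = {"alert": "stationary", "resting": "stationary",
            "walking": "walking", "grazing": "grazing", "flying": "flying"}


# -- ODBA and features ------------------------------------------------

def compute_odba(burst) -> float:
    """ODBA of one burst (mapping or object with x/y/z sample arrays)."""
    x = np.asarray(burst["x"], float)
    y = np.asarray(burst["y"], float)
    z = np.asarray(burst["z"], float)
    n = len(x)
    if n < 2 or len(y) != n or len(z) != n:
        raise ValueError("invalid burst: need three equal axes with n >= 2")
    return float((np.abs(x - x.mean()) + np.abs(y - y.mean())
                  + np.abs(z - z.mean())).sum() / n)


def burst_features(bursts: pd.DataFrame) -> pd.DataFrame:
    """Per-burst classifier features.

    Per-axis mean, SD, min, max and mean absolute deviation, plus ODBA
    and the dominant-axis ratio (largest axis MAD over total).
    """
    rows = []
    for rec in bursts.itertuples():
        feats = {}
        mads = []
        for ax in ("x", "y", "z"):
            v = np.asarray(getattr(rec, ax), float)
            mad = float(np.abs(v - v.mean()).mean())
            mads.append(mad)
            feats.update({f"{ax}_mean": v.mean(), f"{ax}_sd": v.std(),
                          f"{ax}_min": v.min(), f"{ax}_max": v.max(),
                          f"{ax}_mad": mad})
        total = sum(mads)
        feats["odba"] = total
        feats["dominant_axis_ratio"] = max(mads) / total if total > 0 else 1.0 / 3.0
        rows.append(feats)
    return pd.DataFrame(rows, index=bursts.index)


# -- behaviour classification ----------------------------------------

@dataclass
class BehaviorClassifier:
    model: RandomForestClassifier
    feature_names: list
    accuracy: float
    accuracy_ci: tuple
    confusion: pd.DataFrame
    n_train: int
    n_test: int

    def predict(self, bursts: pd.DataFrame) -> pd.DataFrame:
        """Classified bursts with raw and collapsed analysis labels."""
        X = burst_features(bursts)[self.feature_names]
        out = bursts.copy()
        out["predicted"] = self.model.predict(X)
        out["behavior"] = out["predicted"].map(COLLAPSE)
        return out


def train_behavior_classifier(
    bursts: pd.DataFrame,
    split_fraction: float = 0.7,
    seed: int = 0,
    n_estimators: int = 200,
) -> BehaviorClassifier:
    """Random forest on burst features with a stratified 70/30 split.

    Held-out accuracy is reported with a Clopper-Pearson binomial CI
    and a per-class confusion matrix on the raw five classes.
    """
    labels = bursts["label"]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 behaviour classes to train")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"classes too small for a stratified split: {counts[counts < 2].index.tolist()}")
    X = burst_features(bursts)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, train_size=split_fraction, stratify=labels, random_state=seed)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(X_tr, y_tr)
    pred = rf.predict(X_te)
    acc = float((pred == y_te).mean())
    lo, hi = proportion_confint(int((pred == y_te).sum()), len(y_te), method="beta")
    classes = sorted(labels.unique())
    cm = pd.DataFrame(confusion_matrix(y_te, pred, labels=classes),
                      index=classes, columns=classes)
    return BehaviorClassifier(model=rf, feature_names=list(X.columns),
                              accuracy=acc, accuracy_ci=(float(lo), float(hi)),
                              confusion=cm, n_train=len(y_tr), n_test=len(y_te))


# -- activity budgets -------------------------------------------------

def build_budgets(
    classified: pd.DataFrame,
    exposure_records: pd.DataFrame | None = None,
    min_bursts: int = MIN_BURSTS_PER_PERIOD,
    min_days: int = MIN_DAYS_PER_WINTER,
) -> pd.DataFrame:
    """Per goose-day and goose-night behaviour counts.

    Night bursts before local noon belong to the previous evening's
    goose-night; a night inherits the disturbance flag of the day it
    follows.  Days/nights with fewer than ``min_bursts`` bursts are
    dropped, as are individuals with fewer than ``min_days`` distinct
    days in a winter.
    """
    df = classified.copy()
    df["is_night"] = ~solar.is_daytime(df["timestamp"])
    date = df["timestamp"].dt.normalize()
    early = df["timestamp"].dt.hour < 12
    df["date"] = np.where(df["is_night"] & early, date - pd.Timedelta(days=1), date)
    df["date"] = pd.to_datetime(df["date"])

    counts = (df.groupby(["individual_id", "date", "is_night"])["behavior"]
                .value_counts().unstack(fill_value=0))
    for beh in ("grazing", "stationary", "flying", "walking"):
        if beh not in counts:
            counts[beh] = 0
    counts = counts.rename(columns=lambda b: f"bursts_{b}")
    counts["n_bursts"] = counts.sum(axis=1)
    out = counts.reset_index()
    out = out[out["n_bursts"] >= min_bursts]

    out["winter"] = winter_of(out["date"])
    out["date_index"] = date_index_of(out["date"])

    if exposure_records is not None:
        rec = exposure_records[["individual_id", "date", "disturbed",
                                "night_after_disturbed"]]
        out = out.merge(rec, on=["individual_id", "date"], how="left")
        out["disturbed"] = np.where(
            out["is_night"],
            out["night_after_disturbed"].fillna(False),
            out["disturbed"].fillna(False)).astype(bool)
        out = out.drop(columns="night_after_disturbed")
    else:
        out["disturbed"] = False

    days = (out.groupby(["individual_id", "winter"])["date"].transform("nunique"))
    out = out[days >= min_days]
    return out.reset_index(drop=True)


# -- beta-binomial regression ----------------------------------------

class BetaBinomialModel(GenericLikelihoodModel):
    """Beta-binomial regression with a logit link.

    endog is an (n_obs, 2) array of (successes, failures); the last
    parameter is log(theta) where a = theta*pi, b = theta*(1-pi).
    Overdispersion between repeated measures of the same bird is
    absorbed by theta.
    """

    def __init__(self, endog, exog, **kwargs):
        super().__init__(endog, exog, **kwargs)
        k = self.exog.shape[1]
        self._set_extra_params_names(["log_theta"])
        self.start_params = np.r_[np.zeros(k), np.log(10.0)]
        self.df_resid = self.endog.shape[0] - (k + 1)

    def loglike(self, params):
        beta, log_theta = params[:-1], params[-1]
        theta = np.exp(np.clip(log_theta, -20, 20))
        k = self.endog[:, 0]
        n = self.endog.sum(axis=1)
        pi = expit(np.clip(self.exog @ beta, -30, 30))
        a = theta * pi
        b = theta * (1 - pi)
        ll = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
              + betaln(k + a, n - k + b) - betaln(a, b))
        return float(np.sum(ll))


@dataclass
class BudgetFit:
    behavior: str
    formula: str
    params: pd.Series
    se: pd.Series
    aic: float
    theta: float
    n_obs: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.params.index, "estimate": self.params.to_numpy(),
            "se": self.se.to_numpy(),
            "ci_lo": self.params.to_numpy() - 1.96 * self.se.to_numpy(),
            "ci_hi": self.params.to_numpy() + 1.96 * self.se.to_numpy()})


def logit_shift(baseline_proportion: float, shift: float) -> float:
    """Apply a logit-scale coefficient to a baseline proportion."""
    return float(expit(logit(baseline_proportion) + shift))


def _budget_design(df: pd.DataFrame, with_shot: bool, with_interaction: bool) -> str:
    terms = ["C(night_f, Treatment('day'))", "date_s", "date_s2"]
    if with_shot:
        terms.insert(0, "C(shot_f, Treatment('undisturbed'))")
    if with_interaction:
        terms.append("C(shot_f, Treatment('undisturbed')):C(night_f, Treatment('day'))")
    return " + ".join(terms)


def _fit_betabin(df: pd.DataFrame, k_col: str, rhs: str, behavior: str) -> BudgetFit:
    X = patsy.dmatrix("1 + " + rhs, df, return_type="dataframe")
    k = df[k_col].to_numpy(float)
    n = df["n_bursts"].to_numpy(float)
    p = k / n
    if np.all(p == 0) or np.all(p == 1):
        raise ValueError("degenerate dispersion: all proportions are 0 or 1")
    endog = np.column_stack([k, n - k])
    model = BetaBinomialModel(endog, X)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=model.start_params, method="bfgs",
                        maxiter=500, disp=0)
    names = list(X.columns) + ["log_theta"]
    params = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    return BudgetFit(behavior=behavior, formula=rhs, params=params, se=se,
                     aic=float(res.aic), theta=float(np.exp(params["log_theta"])),
                     n_obs=len(df), converged=bool(res.mle_retvals.get("converged", True)))


def fit_budget_model(budgets: pd.DataFrame, behavior: str) -> tuple:
    """Beta-binomial fits of one behaviour's day/night proportions.

    Fits the a priori three-model set — global (Shot, Night, their
    interaction, quadratic date), interaction dropped, and Shot dropped
    — and returns ``(comparison, fits)`` ranked by AIC.
    """
    k_col = f"bursts_{behavior}"
    if k_col not in budgets:
        raise ValueError(f"no counts column '{k_col}' in budget table")
    df = budgets.copy()
    df["shot_f"] = np.where(df["disturbed"], "disturbed", "undisturbed")
    df["night_f"] = np.where(df["is_night"], "night", "day")
    df["date_s"] = df["date_index"].astype(float) / 100.0
    df["date_s2"] = df["date_s"] ** 2

    specs = {
        "global": _budget_design(df, with_shot=True, with_interaction=True),
        "no_interaction": _budget_design(df, with_shot=True, with_interaction=False),
        "no_shot": _budget_design(df, with_shot=False, with_interaction=False),
    }
    fits, rows = {}, []
    for name, rhs in specs.items():
        try:
            fit = _fit_betabin(df, k_col, rhs, behavior)
            fits[name] = fit
            rows.append((name, rhs, len(fit.params), fit.aic, "ok"))
        except Exception as exc:  # noqa: BLE001
            rows.append((name, rhs, np.nan, np.nan, f"failed: {exc}"))
    comp = pd.DataFrame(rows, columns=["model", "formula", "k", "AIC", "status"])
    ok = comp["status"] == "ok"
    comp = pd.concat([comp[ok].sort_values("AIC"), comp[~ok]], ignore_index=True)
    comp["dAIC"] = comp["AIC"] - comp.loc[ok, "AIC"].min()
    return comp, fits


# -- daily ODBA -------------------------------------------------------

def build_odba_daily(
    bursts_with_odba: pd.DataFrame,
    exposure_records: pd.DataFrame | None = None,
    min_days: int = MIN_DAYS_PER_WINTER,
) -> pd.DataFrame:
    """Daily summed daytime ODBA per individual.

    Expects a burst table with an ``odba`` column (see
    :func:`compute_odba`); daytime bursts are summed per goose-day and
    individuals with fewer than ``min_days`` days in a winter excluded.
    """
    df = bursts_with_odba.copy()
    if "odba" not in df:
        df["odba"] = [compute_odba(r) for r in df[["x", "y", "z"]].to_dict("records")]
    df = df[solar.is_daytime(df["timestamp"])].copy()
    df["date"] = df["timestamp"].dt.normalize()
    keys = ["individual_id", "date"]
    extra = {}
    for c in ("species", "sex"):
        if c in df:
            extra[c] = (c, "first")
    out = (df.groupby(keys, as_index=False)
             .agg(total_odba=("odba", "sum"), n_bursts=("odba", "size"), **extra))
    out["winter"] = winter_of(out["date"])
    out["date_index"] = date_index_of(out["date"])
    if exposure_records is not None:
        out = out.merge(exposure_records[["individual_id", "date", "disturbed"]],
                        on=keys, how="left")
        out["disturbed"] = out["disturbed"].fillna(False).astype(bool)
    else:
        out["disturbed"] = False
    days = out.groupby(["individual_id", "winter"])["date"].transform("nunique")
    return out[days >= min_days].reset_index(drop=True)


def odba_model_set() -> dict:
    """Global daily-ODBA model and its four a priori reductions."""
    shot = "C(shot2, Treatment('undisturbed'))"
    base = "sex + date_s + date_s2 + n_bursts"
    return {
        "global": f"total_odba ~ {shot} * species + {base}",
        "no_interaction": f"total_odba ~ {shot} + species + {base}",
        "no_shot": f"total_odba ~ species + {base}",
        "no_species": f"total_odba ~ {shot} + {base}",
        "neither": f"total_odba ~ {base}",
    }


def fit_odba_model(
    odba_daily: pd.DataFrame,
    model_set: dict | None = None,
    use_gee: bool = False,
) -> tuple:
    """Gamma log-link daily-ODBA fits with AIC comparison.

    Returns ``(comparison, fits)``; date enters as a centred/scaled
    quadratic, burst count as a fixed effect, AR1 over each
    individual-winter day series.
    """
    df = odba_daily.copy()
    df["shot2"] = np.where(df["disturbed"], "disturbed", "undisturbed")
    df["date_s"] = (df["date_index"].astype(float) - 90.0) / 100.0
    df["date_s2"] = df["date_s"] ** 2
    df["ind_winter"] = df["individual_id"].astype(str) + ":" + df["winter"].astype(str)
    return compare_models(df, model_set or odba_model_set(),
                          group_col="ind_winter", time_col="date_index",
                          use_gee=use_gee)


def fit_odba_global(odba_daily: pd.DataFrame, use_gee: bool = True) -> GammaAR1Fit:
    """Just the global daily-ODBA model, with AR1-robust covariance."""
    df = odba_daily.copy()
    df["shot2"] = np.where(df["disturbed"], "disturbed", "undisturbed")
    df["date_s"] = (df["date_index"].astype(float) - 90.0) / 100.0
    df["date_s2"] = df["date_s"] ** 2
    df["ind_winter"] = df["individual_id"].astype(str) + ":" + df["winter"].astype(str)
    return fit_gamma_ar1(df, odba_model_set()["global"],
                         group_col="ind_winter", time_col="date_index",
                         use_gee=use_gee)
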