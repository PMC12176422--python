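"""Seminested AICc model comparison of tau burden vs tau spread.

For every outcome the same four models are fit on one identical complete-case
data set and ranked by small-sample corrected AIC:

1. covariate model — age + sex + education only;
2. TI model — covariates + Tau Index;
3. TSS model — covariates + Tau Spatial Spread;
4. additive model — covariates + both metrics.

Three model families share the framework: ordinary least squares for baseline
composite scores, a random-intercept-and-slope mixed model (each term also
interacting with time) for longitudinal composites, and Cox proportional
hazards for clinical conversion. ``AICc = -2 ll + 2K + 2K(K+1)/(n - K - 1)``;
the model with the lowest AICc is nominated and models within 2 AICc of it
are regarded as comparable. The AICc weight ``exp(-d/2) / sum exp(-d/2)`` is
the relative likelihood of each model.

Mixed-model notes: the paper-style default compares restricted log-
likelihoods across models that differ in fixed effects; ``reml=False``
refits by full maximum likelihood (under which the nested-likelihood
ordering is guaranteed). The AICc sample size for the mixed family is the
number of subjects by default ("observations" available), and the number of
events for the Cox family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from sklearn.mixture import GaussianMixture

from .lmm import LMMResult, RandomSlopeLMM

__all__ = [
    "ModelFit",
    "RepresentativeValues",
    "ComparabilityError",
    "aicc",
    "fit_baseline_set",
    "fit_longitudinal_set",
    "fit_survival_set",
    "aicc_compare",
    "gmm_low_high",
    "emm_trajectories",
    "km_median_split",
    "MODEL_NAMES",
    "COMPARABLE_DELTA",
]

MODEL_NAMES = ("Covariate", "TI", "TSS", "Additive")

#: Models within this many AICc units of the best are "comparable".
COMPARABLE_DELTA = 2.0

_COVARIATES = ("age", "sex", "education")


class ComparabilityError(ValueError):
    """Fits being compared were not produced on the same data subset."""


@dataclass
class ModelFit:
    """One member of a seminested set."""

    name: str
    k: int                      # number of estimated parameters
    loglik: float               # maximized (restricted) log-likelihood
    n: int                      # effective sample size for the AICc penalty
    n_obs: int                  # rows actually fit (comparability check)
    aicc: float = field(init=False)
    result: object = None       # underlying fit object
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.aicc = aicc(self.loglik, self.k, self.n)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; +inf when n <= K + 1."""
    if n <= k + 1:
        warnings.warn(f"AICc undefined for K={k} at n={n}; reporting +inf")
        return float("inf")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _model_terms(extra_time_terms: bool = False) -> dict[str, list[str]]:
    base = list(_COVARIATES)
    sets = {
        "Covariate": base,
        "TI": ["TI"] + base,
        "TSS": ["TSS"] + base,
        "Additive": ["TI", "TSS"] + base,
    }
    if extra_time_terms:
        out = {}
        for name, terms in sets.items():
            out[name] = terms + ["visit_time"] + [f"{t}:visit_time" for t in terms]
        return out
    return sets


# ---------------------------------------------------------------------------
# Baseline: ordinary least squares
# ---------------------------------------------------------------------------

def fit_baseline_set(baseline: pd.DataFrame, composite: str,
                     models=MODEL_NAMES) -> list[ModelFit]:
    """Four OLS fits of a baseline composite on one complete-case subset.

    K counts the intercept, the slopes and the residual variance, so the
    additive model has K = 7. The log-likelihood is Gaussian at the MLE.
    """
    import statsmodels.api as sm

    cols = [composite, "TI", "TSS", *_COVARIATES]
    data = baseline.dropna(subset=cols)
    n = len(data)
    fits = []
    for name, terms in _model_terms().items():
        if name not in models:
            continue
        X = sm.add_constant(data[terms].astype(float), has_constant="add")
        k = X.shape[1] + 1  # + residual variance
        if n <= k + 1:
            fits.append(ModelFit(name=name, k=k, loglik=-np.inf, n=n, n_obs=n,
                                 flags=("insufficient_n",)))
            continue
        res = sm.OLS(data[composite].astype(float), X).fit()
        fits.append(ModelFit(name=name, k=k, loglik=float(res.llf), n=n,
                             n_obs=n, result=res))
    return fits


# ---------------------------------------------------------------------------
# Longitudinal: mixed model with random intercept and slope
# ---------------------------------------------------------------------------

def fit_longitudinal_set(long_panel: pd.DataFrame, composite: str,
                         reml: bool = True, n_for_aicc: str = "subjects",
                         models=MODEL_NAMES) -> list[ModelFit]:
    """Four mixed-model fits of a longitudinal composite.

    Each model has every term also interacting with time, plus a correlated
    random intercept and slope per subject. K counts the fixed effects, the
    three random-effect covariance parameters and the residual variance, so
    the additive model has K = 16. ``n_for_aicc`` is ``"subjects"``
    (default) or ``"observations"``.
    """
    if n_for_aicc not in ("subjects", "observations"):
        raise ValueError(f"unknown n_for_aicc {n_for_aicc!r}")
    cols = [composite, "TI", "TSS", *_COVARIATES, "visit_time", "participant_id"]
    data = long_panel.dropna(subset=[c for c in cols if c != "participant_id"])
    n_sub = data["participant_id"].nunique()
    n_obs = len(data)
    fits = []
    for name, terms in _model_terms(extra_time_terms=True).items():
        if name not in models:
            continue
        k = (len(terms) + 1) + 3 + 1  # fixed effects + G params + resid var
        n_eff = n_sub if n_for_aicc == "subjects" else n_obs
        res = RandomSlopeLMM(reml=reml).fit(data, composite, terms)
        flags = tuple(f for f, on in
                      [("singular", res.singular),
                       ("diagonal_refit", res.diagonal_refit)] if on)
        fits.append(ModelFit(name=name, k=k, loglik=res.loglik, n=n_eff,
                             n_obs=n_obs, result=res, flags=flags))
    return fits


# ---------------------------------------------------------------------------
# Survival: Cox proportional hazards
# ---------------------------------------------------------------------------

def fit_survival_set(survival: pd.DataFrame, n_for_aicc: str = "events",
                     models=MODEL_NAMES) -> list[ModelFit]:
    """Four Cox fits of time to first CDR > 0 (Efron tie handling).

    ``survival`` needs columns time, status, TI, TSS, age, sex, education,
    restricted upstream to baseline-CDR-0 participants. K is the number of
    covariates (TI model K = 4); the log-likelihood is the maximized partial
    likelihood. ``n_for_aicc`` is ``"events"`` (default) or ``"subjects"``.
    """
    if n_for_aicc not in ("events", "subjects"):
        raise ValueError(f"unknown n_for_aicc {n_for_aicc!r}")
    cols = ["time", "status", "TI", "TSS", *_COVARIATES]
    data = survival.dropna(subset=cols)
    n_events = int(data["status"].sum())
    if n_events == 0:
        raise ValueError("no conversion events; Cox models undefined")
    n_eff = n_events if n_for_aicc == "events" else len(data)
    fits = []
    for name, terms in _model_terms().items():
        if name not in models:
            continue
        sub = data[["time", "status", *terms]].astype(float)
        cph = CoxPHFitter()
        flags: tuple[str, ...] = ()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(sub, duration_col="time", event_col="status")
        except ConvergenceError:
            # monotone likelihood / separation: ridge-stabilized refit
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(sub, duration_col="time", event_col="status")
            flags = ("penalized_refit",)
        fits.append(ModelFit(name=name, k=len(terms),
                             loglik=float(cph.log_likelihood_), n=n_eff,
                             n_obs=len(data), result=cph, flags=flags))
    return fits


# ---------------------------------------------------------------------------
# Comparison table
# ---------------------------------------------------------------------------

def aicc_compare(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank a seminested set by AICc.

    Returns a table sorted ascending by AICc with columns model, K,
    loglik, AICc, delta_aicc, weight, nominated, comparable. Raises
    :class:`ComparabilityError` if the members were fit on different rows.
    """
    if len(fits) < 2:
        f = fits[0]
        return pd.DataFrame([{"model": f.name, "K": f.k, "loglik": f.loglik,
                              "AICc": f.aicc, "delta_aicc": 0.0, "weight": 1.0,
                              "nominated": True, "comparable": True,
                              "n": f.n, "flags": ";".join(f.flags)}])
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ComparabilityError(f"fits use different data subsets: rows {n_obs}")
    finite = [f for f in fits if np.isfinite(f.aicc)]
    if len(finite) < 2:
        raise ComparabilityError("need at least 2 finite-AICc fits to compare")
    best = min(f.aicc for f in finite)
    rows = []
    for f in fits:
        delta = f.aicc - best
        rows.append({"model": f.name, "K": f.k, "loglik": f.loglik,
                     "AICc": f.aicc, "delta_aicc": delta, "n": f.n,
                     "flags": ";".join(f.flags)})
    table = pd.DataFrame(rows).sort_values("AICc", kind="stable")
    w = np.exp(-0.5 * table["delta_aicc"].to_numpy())
    w[~np.isfinite(w)] = 0.0
    table["weight"] = w / w.sum()
    table["nominated"] = table["delta_aicc"] == 0.0
    table["comparable"] = table["delta_aicc"] < COMPARABLE_DELTA
    cols = ["model", "K", "loglik", "AICc", "delta_aicc", "weight",
            "nominated", "comparable", "n", "flags"]
    return table[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Representative low/high values and marginal trajectories
# ---------------------------------------------------------------------------

@dataclass
class RepresentativeValues:
    """Low/high component means of a two-component Gaussian mixture."""

    metric: str
    low: float
    high: float
    weights: tuple[float, float] = (0.5, 0.5)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.low < self.high


def gmm_low_high(values, metric: str = "metric",
                 seed: int = 0) -> RepresentativeValues:
    """Two-component univariate Gaussian mixture by EM.

    Deterministic initialization (k-means++ with a fixed seed, best of 10
    restarts by likelihood); component means returned sorted low < high.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise ValueError(f"need at least 20 finite values, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all values identical")
    span = float(np.ptp(values))
    gm = GaussianMixture(n_components=2, n_init=10, init_params="k-means++",
                         random_state=seed, max_iter=500, tol=1e-8,
                         reg_covar=(1e-6 * span) ** 2)
    gm.fit(values.reshape(-1, 1))
    means = gm.means_.ravel()
    order = np.argsort(means)
    flags = ()
    if np.sqrt(gm.covariances_.ravel().min()) <= 1.5e-6 * span:
        flags = ("variance_floor",)
    low, high = float(means[order[0]]), float(means[order[1]])
    if low == high:
        raise ValueError("mixture components collapsed to one mean")
    return RepresentativeValues(metric=metric, low=low, high=high,
                                weights=tuple(gm.weights_[order]), flags=flags)


def emm_trajectories(fit: LMMResult, metric: str, rep: RepresentativeValues,
                     covariate_means: dict[str, float],
                     data_range: tuple[float, float] | None = None
                     ) -> pd.DataFrame:
    """Estimated marginal mean trajectories at the low/high metric values.

    Predicted composite intercept and annual slope at ``metric`` = low and
    high, other covariates held at their sample means, with standard errors
    from the fixed-effect covariance.
    """
    if data_range is not None and not (
            data_range[0] <= rep.low and rep.high <= data_range[1]):
        warnings.warn("representative values outside the observed data range; "
                      "trajectories are extrapolations")
    names = fit.names
    rows = []
    for level, value in (("low", rep.low), ("high", rep.high)):
        c_int = np.zeros(len(names))
        c_slo = np.zeros(len(names))
        for i, name in enumerate(names):
            if name == "Intercept":
                c_int[i] = 1.0
            elif name == "visit_time":
                c_slo[i] = 1.0
            elif name.endswith(":visit_time"):
                term = name.split(":")[0]
                c_slo[i] = value if term == metric else covariate_means[term]
            else:
                c_int[i] = value if name == metric else covariate_means[name]
        rows.append({
            "level": level, "metric": metric, "value": value,
            "intercept": float(c_int @ fit.params),
            "slope": float(c_slo @ fit.params),
            "se_intercept": float(np.sqrt(c_int @ fit.cov_params @ c_int)),
            "se_slope": float(np.sqrt(c_slo @ fit.cov_params @ c_slo)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier median split
# ---------------------------------------------------------------------------

def km_median_split(survival: pd.DataFrame, metric: str,
                    ties_low: bool = True):
    """Product-limit curves after a median split on a baseline tau metric.

    Ties at the median go to the low group by default. Returns
    ``(curves, cut, fitters)``: a tidy table of per-group step-function
    points with Greenwood confidence intervals, the median cut value, and
    the fitted :class:`~lifelines.KaplanMeierFitter` per group.
    """
    data = survival.dropna(subset=["time", "status", metric])
    if int(data["status"].sum()) < 1:
        warnings.warn("no events; survival is identically 1 in both groups")
    values = data[metric].to_numpy(float)
    cut = float(np.median(values))
    low_mask = values <= cut if ties_low else values < cut
    groups = {"low": data[low_mask], "high": data[~low_mask]}
    for name, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"{name} group is empty after the median split")
    fitters, frames = {}, []
    for name, g in groups.items():
        km = KaplanMeierFitter(label=f"{metric} {name}")
        km.fit(g["time"], g["status"])
        fitters[name] = km
        sf = km.survival_function_
        ci = km.confidence_interval_
        frames.append(pd.DataFrame({
            "group": name, "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
            "ci_lower": ci.iloc[:, 0].to_numpy(float),
            "ci_upper": ci.iloc[:, 1].to_numpy(float),
            "n_at_risk": [km.event_table.loc[:t, "at_risk"].iloc[-1]
                          if len(km.event_table.loc[:t]) else len(g)
                          for t in sf.index],
        }))
    curves = pd.concat(frames, ignore_index=True)
    return curves, cut, fitters
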