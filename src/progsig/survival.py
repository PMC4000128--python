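"""Survival-analysis stack for signature evaluation.

Kaplan-Meier curves, log-rank tests, Cox proportional-hazards fits with
standardized hazard ratios, Harrell's concordance index, proportion of
explained variation (PVE), Grambsch-Therneau proportional-hazards
diagnostics on scaled Schoenfeld residuals, follow-up interval
restriction, and Aalen additive cumulative regression.

Cox partial-likelihood maximization is delegated to lifelines (Efron
ties, the default) or statsmodels PHReg (Breslow ties); everything with
a bespoke definition here — the usable-pair concordance, the PVE
transform, interval restriction, the Aalen least-squares accumulation —
is implemented directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

TiesMethod = Literal["efron", "breslow"]
TimeTransform = Literal["km", "identity", "rank", "log"]


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMCurve:
    """Product-limit survival curve with log-log pointwise 95% CI."""

    times: np.ndarray  # observed event times (ascending)
    survival: np.ndarray  # S(t) at each event time
    at_risk: np.ndarray  # number at risk just before each time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.survival,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
                "at_risk": self.at_risk,
                "group": self.label,
            }
        )


def km_estimate(times, events, *, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    CI is the exponential Greenwood (log-log) interval, which stays
    inside [0, 1].
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    event_rows = tab[tab["observed"] > 0]
    grid = event_rows.index.to_numpy(dtype=float)
    if grid.size == 0:  # all censored
        return KMCurve(
            times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([]),
            ci_lower=np.array([]),
            ci_upper=np.array([]),
            label=label,
        )
    surv = kmf.survival_function_at_times(grid).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lower = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    upper = np.interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=float),
        ci_lower=lower,
        ci_upper=upper,
        label=label,
    )


def logrank(groups: dict[str, tuple[Sequence[float], Sequence[int]]]):
    """k-sample log-rank test; returns (chi2 statistic, p) with k-1 df."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for name, (t, e) in groups.items():
        times.extend(np.asarray(t, dtype=float))
        events.extend(np.asarray(e, dtype=int))
        labels.extend([name] * len(t))
    if sum(events) == 0:
        raise ValueError("log-rank undefined with zero events")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxResult:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate: coef, se, HR = exp(coef),
    95% CI, p. Hazard ratios from standardized covariates read as "per
    one standard deviation".
    """

    summary: pd.DataFrame
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: TiesMethod
    strata: Optional[list[str]] = None
    _fitter: object = field(default=None, repr=False)
    _data: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def covariates(self) -> list[str]:
        return self.summary.index.tolist()

    def hr(self, covariate: str | None = None) -> float:
        cov = covariate or self.summary.index[0]
        return float(self.summary.loc[cov, "hr"])

    def ci(self, covariate: str | None = None) -> tuple[float, float]:
        cov = covariate or self.summary.index[0]
        return (
            float(self.summary.loc[cov, "ci_low"]),
            float(self.summary.loc[cov, "ci_high"]),
        )

    def p(self, covariate: str | None = None) -> float:
        cov = covariate or self.summary.index[0]
        return float(self.summary.loc[cov, "p"])


def _as_cox_frame(X: pd.DataFrame, times, events, strata) -> pd.DataFrame:
    df = X.copy().astype(float)
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    if strata is not None:
        df["_stratum"] = np.asarray(strata)
    if df[["_time"]].isna().any().any() or not np.isfinite(df.drop(columns="_stratum", errors="ignore").to_numpy(dtype=float)).all():
        raise ValueError("covariates and times must be finite")
    return df


def cox_fit(
    X: pd.DataFrame,
    times,
    events,
    *,
    ties: TiesMethod = "efron",
    strata=None,
) -> CoxResult:
    """Maximize the Cox partial likelihood.

    ``strata`` (e.g. the cohort label) gives each stratum its own
    baseline hazard without forcing proportional stratum effects —
    the cohort-adjustment device. Efron tie handling is the default;
    Breslow is routed through statsmodels PHReg.
    """
    X = pd.DataFrame(X)
    ev = np.asarray(events, dtype=int)
    if ev.sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
    df = _as_cox_frame(X, times, ev, strata)
    if ties == "efron":
        return _cox_fit_lifelines(df, X.columns.tolist(), strata is not None)
    if ties == "breslow":
        return _cox_fit_phreg(df, X.columns.tolist(), strata is not None)
    raise ValueError(f"unknown ties method {ties!r}")


def _cox_fit_lifelines(df: pd.DataFrame, covs: list[str], stratified: bool) -> CoxResult:
    cph = CoxPHFitter()
    try:
        cph.fit(
            df,
            duration_col="_time",
            event_col="_event",
            strata=["_stratum"] if stratified else None,
        )
    except ConvergenceError as err:
        raise ValueError(f"Cox model failed to converge: {err}") from err
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
            "p": s["p"],
        }
    ).loc[covs]
    llr = cph.log_likelihood_ratio_test()
    loglik = float(cph.log_likelihood_)
    loglik_null = loglik - float(llr.test_statistic) / 2.0
    return CoxResult(
        summary=summary,
        loglik=loglik,
        loglik_null=loglik_null,
        n=len(df),
        n_events=int(df["_event"].sum()),
        ties="efron",
        strata=sorted(df["_stratum"].unique().tolist()) if stratified else None,
        _fitter=cph,
        _data=df,
    )


def _cox_fit_phreg(df: pd.DataFrame, covs: list[str], stratified: bool) -> CoxResult:
    from statsmodels.duration.hazard_regression import PHReg

    model = PHReg(
        df["_time"].to_numpy(),
        df[covs].to_numpy(),
        status=df["_event"].to_numpy(),
        ties="breslow",
        strata=df["_stratum"].to_numpy() if stratified else None,
    )
    res = model.fit()
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    z = 1.959963984540054
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "p": 2 * stats.norm.sf(np.abs(coef / se)),
        },
        index=covs,
    )
    loglik = float(model.loglike(coef))
    loglik_null = float(model.loglike(np.zeros_like(coef)))
    return CoxResult(
        summary=summary,
        loglik=loglik,
        loglik_null=loglik_null,
        n=len(df),
        n_events=int(df["_event"].sum()),
        ties="breslow",
        strata=sorted(df["_stratum"].unique().tolist()) if stratified else None,
        _fitter=res,
        _data=df,
    )


# ---------------------------------------------------------------------------
# Concordance index


@dataclass
class ConcordanceResult:
    """Harrell's C over usable (orderable-under-censoring) pairs."""

    c: float
    ci_low: float
    ci_high: float
    n_usable_pairs: int


def concordance(scores, times, events, *, alpha: float = 0.05) -> ConcordanceResult:
    """Harrell's concordance index for a censored endpoint.

    A pair is usable when censoring still reveals who failed first: the
    earlier time is an event, or the times tie with exactly one event.
    Credit 1 when the earlier failure has the higher score, 1/2 on score
    ties. CI is an asymptotic normal interval on the usable-pair
    proportion, clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(s)
    if not (len(t) == len(e) == n):
        raise ValueError("scores, times and events must be equal length")
    # orderable(i, j): i demonstrably fails before j
    dt = t[:, None] - t[None, :]
    first_i = (dt < 0) & (e[:, None] == 1)
    tie_t = (dt == 0) & (e[:, None] == 1) & (e[None, :] == 0)
    i_first = first_i | tie_t
    ds = s[:, None] - s[None, :]
    concordant = (i_first & (ds > 0)).sum()
    tied_score = (i_first & (ds == 0)).sum()
    usable = int(i_first.sum())
    if usable == 0:
        raise ValueError("no usable pairs (censoring hides every ordering)")
    c = (concordant + 0.5 * tied_score) / usable
    se = np.sqrt(c * (1 - c) / usable)
    z = stats.norm.ppf(1 - alpha / 2)
    return ConcordanceResult(
        c=float(c),
        ci_low=float(max(0.0, c - z * se)),
        ci_high=float(min(1.0, c + z * se)),
        n_usable_pairs=usable,
    )


# ---------------------------------------------------------------------------
# Explained variation


def pve(result: CoxResult) -> float:
    """Proportion of variation explained: 1 - exp(-G/n).

    G is the likelihood-ratio statistic 2(loglik_model - loglik_null).
    This is the Cox-Snell style transform of the partial-likelihood
    ratio; it lies in [0, 1) and is 0 for an uninformative covariate.
    """
    if result.loglik_null is None or np.isnan(result.loglik_null):
        raise ValueError("fit does not carry a null log-likelihood")
    g = 2.0 * (result.loglik - result.loglik_null)
    return float(1.0 - np.exp(-max(g, 0.0) / result.n))


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics


@dataclass
class PHTestResult:
    """Grambsch-Therneau test per covariate.

    ``rho`` is the Pearson correlation of the scaled Schoenfeld
    residuals with the transformed event time; a decaying effect shows
    up as rho < 0.
    """

    rho: pd.Series
    p: pd.Series
    transform: TimeTransform


def ph_test(result: CoxResult, *, transform: TimeTransform = "km") -> PHTestResult:
    """Test proportional hazards via scaled Schoenfeld residuals.

    The residuals estimate beta(t) - beta_hat at each event time;
    correlation with transformed time indicates a time-varying effect.
    p-values come from the Grambsch-Therneau score statistic.
    """
    if result._fitter is None or not isinstance(result._fitter, CoxPHFitter):
        raise ValueError("ph_test requires an Efron (lifelines) Cox fit")
    df = result._data
    if int(df["_event"].sum()) < 3:
        raise ValueError("too few events for a PH test")
    cph: CoxPHFitter = result._fitter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        test = proportional_hazard_test(cph, df, time_transform=transform)
        resid = cph.compute_residuals(df, kind="scaled_schoenfeld")
    ev = df.loc[resid.index]
    tt = _transform_times(ev["_time"].to_numpy(dtype=float), df, transform)
    order = np.argsort(ev["_time"].to_numpy())
    rho = {}
    for cov in result.covariates:
        r = resid[cov].to_numpy(dtype=float)[order]
        g = tt[order]
        rho[cov] = float(stats.pearsonr(g, r)[0]) if len(r) > 2 else np.nan
    psum = test.summary["p"]
    if isinstance(psum.index, pd.MultiIndex):
        psum = psum.droplevel(1)
    p = pd.Series({cov: float(psum.loc[cov]) for cov in result.covariates})
    return PHTestResult(rho=pd.Series(rho), p=p, transform=transform)


def _transform_times(event_times: np.ndarray, df: pd.DataFrame, transform: TimeTransform) -> np.ndarray:
    if transform == "identity":
        return event_times
    if transform == "log":
        return np.log(event_times)
    if transform == "rank":
        return stats.rankdata(event_times)
    if transform == "km":
        kmf = KaplanMeierFitter().fit(df["_time"], df["_event"])
        surv = kmf.survival_function_["KM_estimate"]
        # left-continuous KM evaluated just before each event time
        idx = np.searchsorted(surv.index.to_numpy(), event_times, side="left") - 1
        s_minus = np.where(idx >= 0, surv.to_numpy()[np.maximum(idx, 0)], 1.0)
        return 1.0 - s_minus
    raise ValueError(f"unknown time transform {transform!r}")


# ---------------------------------------------------------------------------
# Interval restriction


def restrict_interval(times, events, lower: float, upper: float):
    """Reduce follow-up to the sub-experiment of [lower, upper).

    Subjects who failed or were censored before ``lower`` leave the risk
    set and are excluded. Subjects with an event or censoring inside the
    window keep their original time and status; subjects still at risk
    at ``upper`` are administratively censored there. Returns
    (times, events, included) as numpy arrays, with ``included`` a
    boolean mask into the original arrays.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (0 <= lower < upper):
        raise ValueError(f"need 0 <= lower < upper, got [{lower}, {upper})")
    included = t >= lower
    t_out = t[included].copy()
    e_out = e[included].copy()
    beyond = t_out >= upper
    t_out[beyond] = upper
    e_out[beyond] = 0
    return t_out, e_out, included


# ---------------------------------------------------------------------------
# Aalen additive cumulative regression


@dataclass
class AalenResult:
    """Cumulative regression coefficients B(t) of an additive-hazards model.

    The hazard is modeled as b0(t) + b1(t) * z; the estimate accumulates
    least-squares increments at event times, so a time-constant effect
    appears as a straight line of slope b1. ``truncated_at`` records the
    time at which accumulation stopped if the design became singular.
    """

    times: np.ndarray
    cumulative: pd.DataFrame  # columns: intercept + covariates
    variance: pd.DataFrame
    ci_lower: pd.DataFrame
    ci_upper: pd.DataFrame
    truncated_at: Optional[float] = None

    def as_frame(self, covariate: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.cumulative[covariate].to_numpy(),
                "lower": self.ci_lower[covariate].to_numpy(),
                "upper": self.ci_upper[covariate].to_numpy(),
            }
        )


def aalen_cumulative(covariate, times, events, *, alpha: float = 0.05) -> AalenResult:
    """Aalen's additive-hazards estimator for one covariate.

    At each event time, the increment is the least-squares solution
    (X'X)^-1 X' dN over the risk set with design X = [1, z]; cumulative
    variance accumulates the squared increments. Accumulation stops (and
    ``truncated_at`` is set) if the design loses rank, e.g. when the
    covariate becomes constant in the shrinking risk set.
    """
    z = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 2:
        raise ValueError("Aalen estimator needs at least 2 events")
    if np.unique(z).size < 2:
        raise ValueError("covariate is constant")
    cols = ["intercept", "covariate"]
    event_times = np.unique(t[e == 1])
    B = np.zeros(2)
    V = np.zeros((2, 2))
    grid, cum, var = [], [], []
    truncated_at = None
    for tk in event_times:
        at_risk = t >= tk
        X = np.column_stack([np.ones(at_risk.sum()), z[at_risk]])
        xtx = X.T @ X
        if np.linalg.matrix_rank(xtx) < 2:
            truncated_at = float(tk)
            break
        dN = ((t[at_risk] == tk) & (e[at_risk] == 1)).astype(float)
        Xinv = np.linalg.solve(xtx, X.T)  # (X'X)^-1 X'
        db = Xinv @ dN
        B = B + db
        V = V + (Xinv * dN) @ Xinv.T
        grid.append(tk)
        cum.append(B.copy())
        var.append(np.diag(V).copy())
    zq = stats.norm.ppf(1 - alpha / 2)
    cum_df = pd.DataFrame(cum, columns=cols)
    var_df = pd.DataFrame(var, columns=cols)
    sd = np.sqrt(var_df)
    return AalenResult(
        times=np.asarray(grid, dtype=float),
        cumulative=cum_df,
        variance=var_df,
        ci_lower=cum_df - zq * sd,
        ci_upper=cum_df + zq * sd,
        truncated_at=truncated_at,
    )
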