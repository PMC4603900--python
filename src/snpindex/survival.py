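"""Survival inference primitives: Kaplan-Meier, log-rank, Cox PH.

Thin, validated wrappers with stable return types used by every
downstream stage.  Cox fitting uses the Efron approximation for tied
event times by default (month-resolution follow-up produces heavy
tying); a Breslow-ties fit is available behind ``ties="breslow"`` for
cross-checks.  Inference is Wald throughout: log-scale 95% confidence
intervals and two-sided p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test


class NonIdentifiableError(ValueError):
    """The design contains a covariate the partial likelihood cannot identify."""


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; ``at_risk[i]``
    and ``n_events[i]`` are the risk-set size and death count at that
    time; ``variance`` is the Greenwood variance of S(t).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if self.survival.size and (np.any(np.diff(self.survival) > 1e-12)
                                   or self.survival[0] > 1 + 1e-12):
            raise ValueError("survival must be nonincreasing and start <= 1")


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit with Wald inference per covariate."""

    labels: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    ties: str

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> np.ndarray:
        """(k, 2) array of log-scale Wald 95% CIs on the HR scale."""
        z = stats.norm.ppf(0.975)
        with np.errstate(over="ignore"):  # huge SE -> inf upper bound
            return np.column_stack([np.exp(self.coef - z * self.se),
                                    np.exp(self.coef + z * self.se)])

    @property
    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def __getitem__(self, label: str) -> dict:
        i = self.labels.index(label)
        return {"coef": float(self.coef[i]), "se": float(self.se[i]),
                "hr": float(self.hr[i]),
                "ci95": (float(self.ci95[i, 0]), float(self.ci95[i, 1])),
                "p": float(self.wald_p[i])}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hr": self.hr,
            "ci_low": self.ci95[:, 0], "ci_high": self.ci95[:, 1],
            "p": self.wald_p}, index=list(self.labels))


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("negative time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    Censored-only input yields an empty event grid, i.e. S(t) = 1
    everywhere.
    """
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    if ev.empty:
        z = np.array([])
        return KMCurve(z, z, z, z, z)
    event_times = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[event_times, "KM_estimate"].to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum d/(n(n-d)); undefined once S hits 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
        var = surv ** 2 * np.cumsum(terms)
    var = np.where(np.isfinite(var), var, np.nan)
    return KMCurve(event_times, surv, n.astype(int), d.astype(int), var)


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value of S at time ``t``.

    Returns 1 before the first event and carries the last value forward
    beyond the final observed event time.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if curve.event_times.size == 0:
        return 1.0
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank_test(times, events, groups) -> LogRankResult:
    """K-sample log-rank test (observed-minus-expected, hypergeometric
    variance summed over distinct event times); chi-square on k-1 df."""
    t, e = _check_times_events(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must have the same length as times")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank requires at least 2 nonempty groups")
    res = multivariate_logrank_test(t, g, e)
    df = int(labels.size - 1)
    stat = float(res.test_statistic)
    return LogRankResult(stat, df, float(stats.chi2.sf(stat, df)))


def _as_design(design, labels) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        X = design.reset_index(drop=True)
        if labels is not None:
            X.columns = list(labels)
    else:
        arr = np.atleast_2d(np.asarray(design, dtype=float))
        if arr.shape[0] == 1 and labels is not None and len(labels) == 1:
            arr = arr.T
        if labels is None:
            labels = [f"x{i}" for i in range(arr.shape[1])]
        X = pd.DataFrame(arr, columns=list(labels))
    return X


def cox_fit(times, events, design, labels: Optional[Sequence[str]] = None,
            ties: str = "efron") -> CoxFit:
    """Fit a Cox PH model by maximum partial likelihood.

    ``design`` is an (n, k) covariate matrix or DataFrame with no
    missing values.  Constant columns are rejected as non-identifiable;
    complete separation is reported via ``converged=False``.
    """
    t, e = _check_times_events(times, events)
    if e.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    X = _as_design(design, labels)
    if len(X) != t.size:
        raise ValueError("design row count must match times")
    if X.isna().any().any():
        raise ValueError("design contains missing values")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise NonIdentifiableError(
            f"constant covariate(s) {const}: coefficient not identifiable")
    if ties == "breslow":
        return _cox_fit_breslow(t, e, X)
    if ties != "efron":
        raise ValueError("ties must be 'efron' or 'breslow'")

    df = X.copy()
    df["__t"] = t
    df["__e"] = e
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="__t", event_col="__e",
                    fit_options={"precision": 1e-9, "max_steps": 500})
        except ConvergenceError as err:
            raise NonIdentifiableError(f"Cox fit failed to converge: {err}") from None
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    coef = cph.params_.to_numpy(dtype=float)
    se = cph.standard_errors_.to_numpy(dtype=float)
    if np.any(np.abs(coef) > 15):  # divergence: effectively complete separation
        converged = False
    return CoxFit(tuple(X.columns), coef, se, float(cph.log_likelihood_),
                  int(t.size), int(e.sum()), converged, "efron")


def _cox_fit_breslow(t: np.ndarray, e: np.ndarray, X: pd.DataFrame) -> CoxFit:
    """Newton-Raphson maximization of the Breslow-ties partial likelihood.

    Gradient max-norm < 1e-8 declares convergence; step-halving guards
    against likelihood decrease; 50 iterations maximum.
    """
    Xa = X.to_numpy(dtype=float)
    n, k = Xa.shape
    order = np.argsort(-t)  # decreasing time: risk set = prefix
    t_s, e_s, X_s = t[order], e[order], Xa[order]

    def loglik_grad_hess(beta):
        eta = X_s @ beta
        eta -= eta.max()
        w = np.exp(eta)
        cw = np.cumsum(w)                      # sum over risk set (ties at
        cwx = np.cumsum(w[:, None] * X_s, axis=0)   # equal times handled below)
        cwxx = np.cumsum(w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)
        # risk set for time t includes all with time >= t: extend prefix over ties
        idx = np.searchsorted(-t_s, -t_s, side="right") - 1
        ll, g, H = 0.0, np.zeros(k), np.zeros((k, k))
        for i in np.flatnonzero(e_s == 1):
            j = idx[i]
            S0, S1, S2 = cw[j], cwx[j], cwxx[j]
            ll += eta[i] - np.log(S0)
            g += X_s[i] - S1 / S0
            H -= S2 / S0 - np.outer(S1, S1) / S0 ** 2
        return ll, g, H

    beta = np.zeros(k)
    ll, g, H = loglik_grad_hess(beta)
    converged = False
    for _ in range(50):
        if np.max(np.abs(g)) < 1e-8:
            converged = True
            break
        step = np.linalg.solve(H, -g)
        scale = 1.0
        for _ in range(30):  # step-halving on likelihood decrease
            new_beta = beta + scale * step
            new_ll, new_g, new_H = loglik_grad_hess(new_beta)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2
        beta, ll, g, H = new_beta, new_ll, new_g, new_H
    else:
        converged = np.max(np.abs(g)) < 1e-8
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov))
    if np.any(np.abs(beta) > 15):
        converged = False
    return CoxFit(tuple(X.columns), beta, se, float(ll),
                  int(n), int(e.sum()), converged, "breslow")
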