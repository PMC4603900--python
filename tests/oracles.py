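"""Independent brute-force oracles used by the test suite.

Plain-loop implementations of the exact Cox partial likelihood (Efron
and Breslow tie handling), the product-limit estimator, and the
two-group log-rank statistic.  Deliberately slow and dependency-free so
they stay independent of the package's fitting code.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def efron_loglik(beta: float, times, events, x) -> float:
    """Exact Efron-ties partial log-likelihood for one covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        D = [i for i in range(len(times)) if times[i] == t and events[i] == 1]
        R = [i for i in range(len(times)) if times[i] >= t]
        d = len(D)
        sum_r = sum(math.exp(beta * x[i]) for i in R)
        sum_d = sum(math.exp(beta * x[i]) for i in D)
        ll += sum(beta * x[i] for i in D)
        for j in range(d):
            ll -= math.log(sum_r - (j / d) * sum_d)
    return ll


def breslow_loglik(beta: float, times, events, x) -> float:
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = sum(math.exp(beta * x[j]) for j in range(len(times))
                   if times[j] >= times[i])
        ll += beta * x[i] - math.log(risk)
    return ll


def grid_max(loglik, times, events, x, lo=-5.0, hi=5.0) -> float:
    """1-D maximizer of a partial likelihood, to high precision."""
    res = minimize_scalar(lambda b: -loglik(b, times, events, x),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def cox_score_test_stat(times, events, x) -> float:
    """Untied-data Cox score test statistic U(0)^2 / I(0)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    U = 0.0
    I = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        R = [j for j in range(len(times)) if times[j] >= times[i]]
        xbar = sum(x[j] for j in R) / len(R)
        x2bar = sum(x[j] ** 2 for j in R) / len(R)
        U += x[i] - xbar
        I += x2bar - xbar ** 2
    return U ** 2 / I


def hand_km(times, events):
    """Product-limit curve: list of (t, S(t)) at event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (n - d) / n
        out.append((t, s))
    return out


def hand_logrank_2group(times, events, group):
    """Two-group log-rank: (O1-E1)^2 / V with hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    OmE = 0.0
    V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (group == 1)).sum())
        OmE += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return OmE ** 2 / V


def hand_hwe_chi2(n_ww, n_wv, n_vv) -> float:
    n = n_ww + n_wv + n_vv
    q = (n_wv + 2 * n_vv) / (2 * n)
    exp = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q ** 2]
    obs = [n_ww, n_wv, n_vv]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


def hand_pearson_chi2(table) -> float:
    table = np.asarray(table, float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat
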