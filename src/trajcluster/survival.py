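"""Survival analysis from first principles: product-limit estimator,
log-rank tests and Cox proportional-hazards regression.

All estimators are implemented directly from their defining formulas (the
test-suite cross-checks them against independent references).  Times are
days since the index event; deaths precede censorings at tied times.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KMEstimate", "CoxFit", "km_fit", "log_rank", "cox_fit",
           "build_survival_records", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate evaluated at the distinct death times."""

    times: np.ndarray      # distinct event (death) times, increasing
    n_risk: np.ndarray     # at-risk counts just before each time
    n_events: np.ndarray   # deaths at each time
    survival: np.ndarray   # S(t) after each time

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_times(time: np.ndarray) -> np.ndarray:
    time = np.asarray(time, dtype=float)
    if (time <= 0).any():
        raise ValueError("follow-up times must be > 0")
    return time


def km_fit(time, event) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over death times t_i <= t of (1 - d_i / n_i), with n_i the
    number still at risk just before t_i (censorings tied with a death time
    are counted as at risk at that time).
    """
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("at least one record required")
    death_times = np.unique(time[event == 1])
    n_risk = np.array([(time >= t).sum() for t in death_times], dtype=int)
    n_events = np.array([((time == t) & (event == 1)).sum() for t in death_times],
                        dtype=int)
    with np.errstate(divide="ignore"):
        surv = np.cumprod(1.0 - n_events / n_risk)
    return KMEstimate(times=death_times, n_risk=n_risk, n_events=n_events,
                      survival=surv)


def log_rank(time, event, group, pairwise: bool = False):
    """Log-rank test across groups.

    Global mode returns ``(statistic, df, p)`` with the usual O-E sums and
    hypergeometric covariance (one group dropped, generalised via solve).
    ``pairwise=True`` instead returns a DataFrame with one two-group test
    per pair of labels.
    """
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    if event.sum() == 0:
        raise ValueError("log-rank requires at least 1 event")
    for g in labels:
        if not (group == g).any():
            raise ValueError(f"group {g!r} has no members at risk")

    if pairwise:
        rows = []
        for a, b in combinations(labels, 2):
            sel = (group == a) | (group == b)
            stat, df, p = log_rank(time[sel], event[sel], group[sel])
            rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_value": p})
        return pd.DataFrame(rows)

    G = len(labels)
    gidx = np.searchsorted(labels, group)
    death_times = np.unique(time[event == 1])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for t in death_times:
        at_risk = time >= t
        n = at_risk.sum()
        n_g = np.bincount(gidx[at_risk], minlength=G).astype(float)
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d_g = np.bincount(gidx[dying], minlength=G).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            V += factor * (np.diag(n_g) * n - np.outer(n_g, n_g)) / n ** 2
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    stat = float(z @ np.linalg.solve(Vr, z)) if len(z) else 0.0
    df = G - 1
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass(frozen=True)
class CoxFit:
    """Fitted proportional-hazards model (partial likelihood)."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def confidence_intervals(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.coef - z * self.se)
        hi = np.exp(self.coef + z * self.se)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.confidence_intervals()
        return pd.DataFrame({
            "covariate": self.names,
            "coef": self.coef,
            "se": self.se,
            "hr": self.hazard_ratios,
            "hr_ci_low": ci[:, 0],
            "hr_ci_high": ci[:, 1],
            "p_value": 2 * stats.norm.sf(np.abs(self.coef / self.se)),
        })


def _cox_loglik_grad_hess(beta, X, time, event, ties="breslow"):
    """Breslow/Efron partial log-likelihood with analytic derivatives."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # decreasing time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta -= eta.max()  # overflow guard; the shift cancels exactly in the loglik
    r = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:  # add the whole risk-set slab for time t
            S0 += r[j]
            S1 += r[j] * Xs[j]
            S2 += r[j] * np.outer(Xs[j], Xs[j])
            j += 1
        dying = [k for k in range(i, j) if es[k] == 1]
        d = len(dying)
        if d:
            xsum = Xs[dying].sum(axis=0)
            ll += float(eta[dying].sum())
            if ties == "efron":
                rd = r[dying].sum()
                S1d = (r[dying, None] * Xs[dying]).sum(axis=0)
                S2d = np.einsum("k,ki,kj->ij", r[dying], Xs[dying], Xs[dying])
                for l in range(d):
                    f = l / d
                    s0 = S0 - f * rd
                    s1 = S1 - f * S1d
                    s2 = S2 - f * S2d
                    ll -= np.log(s0)
                    grad -= s1 / s0
                    hess -= s2 / s0 - np.outer(s1, s1) / s0 ** 2
            else:  # breslow
                ll -= d * np.log(S0)
                grad -= d * S1 / S0
                hess -= d * (S2 / S0 - np.outer(S1, S1) / S0 ** 2)
            grad += xsum
        i = j
    return ll, grad, hess


def cox_fit(X, time, event, names: tuple[str, ...] | None = None,
            ties: str = "breslow", max_iter: int = 50) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    ``X`` may be a DataFrame (column names kept) or an (n, p) array.
    Convergence: max |score| < 1e-8 or relative log-likelihood change
    < 1e-10.  Raises :class:`ConvergenceError` on failure or apparent
    separation (diverging coefficients).
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    names = names or tuple(f"x{i}" for i in range(p))
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    if event.sum() < p:
        raise ValueError("need at least as many events as covariates")
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {names[j]!r} is constant")

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(beta, X, time, event, ties)
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < 1e-8:
            break
        step = np.linalg.solve(-hess, grad)
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, X, time, event, ties)
        halvings = 0
        while new_ll < ll and halvings < 25:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, X, time, event, ties)
            halvings += 1
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(beta).max() > 50:
            raise ConvergenceError(
                f"coefficients diverging (max |beta| = {np.abs(beta).max():.1f}); "
                "possible perfect separation")
        if rel_change < 1e-10 or np.abs(grad).max() < 1e-8:
            break
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(max |score| = {np.abs(grad).max():.3g}, loglik = {ll:.6g})")

    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxFit(names=names, coef=beta, se=se, log_likelihood=float(ll),
                  n_iter=it, converged=True)


def build_survival_records(covariates: pd.DataFrame,
                           labels: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Assemble time/event/covariate records for the post-index follow-up.

    Time runs from the index to death or administrative censoring,
    whichever comes first; a minimum of 1 day is enforced.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("patient_id")["cluster"]
    cov = covariates.set_index("patient_id").loc[labels.index]
    death = cov["death_day"]
    end = cov["followup_end_day"]
    event = (~death.isna()).astype(int)
    time = np.where(event == 1, death, end).astype(float)
    time = np.maximum(time, 1.0)
    out = pd.DataFrame({
        "patient_id": labels.index,
        "time": time,
        "event": event.to_numpy(),
        "age": cov["age"].to_numpy(),
        "male": (cov["sex"] == "male").astype(int).to_numpy(),
        "cluster": labels.to_numpy(),
    })
    return out
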