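"""Kaplan-Meier and Cox proportional-hazards models for boundary crossings.

The quantity modelled is the time (in days, on a gap-time clock that
restarts at every crossing) until a seal performs a cross-boundary
haul-out.  "Survival" at time t is therefore the probability of still being
in the departure jurisdiction t days after entering it.

Two Cox models are provided, both maximizing the Efron-tie partial
likelihood by Newton-Raphson with step-halving:

* :class:`CoxPH` -- fixed effects only,
  ``h(t) = h0(t) * exp(x' beta)``;
* :class:`CoxFrailty` -- adds a Gaussian random intercept (log-normal
  frailty) per seal, ``h(t) = h0(t) * exp(x' beta + b_i)`` with
  ``b_i ~ N(0, sigma_b^2)``.  The random effects are profiled out by an
  inner penalized Newton-Raphson over (beta, b) and the frailty variance is
  maximized on an outer one-dimensional Laplace-approximate marginal
  likelihood.

Hazard ratios are ``exp(beta)`` relative to the reference jurisdiction,
which defaults to the level with the highest empirical crossing rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


class DegeneracyError(ValueError):
    """A covariate carries no information (zero variance)."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class KaplanMeierEstimator:
    """Product-limit estimator of the crossing-time survival function.

    After ``fit``: ``times_`` (ordered distinct event times), ``survival_``
    (S(t) at those times), ``at_risk_``, ``n_events_``, ``variance_``
    (Greenwood), ``median_`` (smallest t with S(t) <= 0.5, or NaN).
    """

    def __init__(self, label: str | None = None):
        self.label = label

    def get_params(self, deep=True):
        return {"label": self.label}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, durations, event_observed):
        t = np.asarray(durations, dtype=float)
        e = np.asarray(event_observed, dtype=int)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("durations and event_observed must be 1-D and equal length")
        if np.any(t <= 0):
            raise ValueError("durations must be positive")
        self.n_subjects_ = t.size
        ev_times = np.unique(t[e == 1])
        surv, var_sum = 1.0, 0.0
        S, V, atrisk, nev = [], [], [], []
        for ti in ev_times:
            n_i = int(np.sum(t >= ti))
            d_i = int(np.sum((t == ti) & (e == 1)))
            surv *= 1.0 - d_i / n_i
            if n_i > d_i:
                var_sum += d_i / (n_i * (n_i - d_i))
                V.append(surv ** 2 * var_sum)
            else:
                V.append(0.0)
            S.append(surv)
            atrisk.append(n_i)
            nev.append(d_i)
        self.times_ = ev_times
        self.survival_ = np.asarray(S)
        self.variance_ = np.asarray(V)
        self.at_risk_ = np.asarray(atrisk, dtype=int)
        self.n_events_ = np.asarray(nev, dtype=int)
        below = np.flatnonzero(self.survival_ <= 0.5)
        self.median_ = float(ev_times[below[0]]) if below.size else np.nan
        return self

    def survival_at(self, t):
        """Step-function value S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times_, t, side="right") - 1
        s = np.where(idx >= 0, np.concatenate([[1.0], self.survival_])[idx + 1], 1.0)
        return s if s.ndim else float(s)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.label, "time": self.times_, "survival": self.survival_,
            "at_risk": self.at_risk_, "events": self.n_events_,
            "greenwood_var": self.variance_,
        })


def km_fit(intervals: pd.DataFrame, group_by: str = "unit") -> dict[str, KaplanMeierEstimator]:
    """Kaplan-Meier curve per level of ``group_by`` from risk intervals."""
    curves = {}
    for label, grp in intervals.groupby(group_by, sort=True):
        if len(grp) == 0:
            warnings.warn(f"group {label!r} has no risk intervals; skipped")
            continue
        dur = (grp["t_stop"] - grp["t_start"]).to_numpy(float)
        curves[str(label)] = KaplanMeierEstimator(label=str(label)).fit(
            dur, grp["event"].to_numpy(int))
    return curves


def median_survival(curve: KaplanMeierEstimator) -> float:
    """Smallest time with S(t) <= 0.5; NaN when S never reaches 0.5."""
    return curve.median_


# ---------------------------------------------------------------------------
# Efron partial likelihood machinery
# ---------------------------------------------------------------------------

def _efron_quantities(theta, X, t, e, order, need_hess=True):
    """Log partial likelihood, score and observed information (Efron ties).

    ``order`` sorts durations descending so the risk set accumulates as we
    walk forward.  Returns (loglik, gradient, information).
    """
    n, p = X.shape
    eta = X @ theta
    c = float(np.max(eta)) if n else 0.0
    w = np.exp(eta - c)
    ll = 0.0
    g = np.zeros(p)
    info = np.zeros((p, p)) if need_hess else None

    ts = t[order]
    ws = w[order]
    Xs = X[order]
    es = e[order]
    # distinct times, descending
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p)) if need_hess else None
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        wb = ws[i:j]
        Xb = Xs[i:j]
        S0 += float(np.sum(wb))
        S1 += wb @ Xb
        if need_hess:
            S2 += Xb.T @ (Xb * wb[:, None])
        dmask = es[i:j] == 1
        m = int(np.sum(dmask))
        if m:
            Xd = Xb[dmask]
            wd = wb[dmask]
            D0 = float(np.sum(wd))
            D1 = wd @ Xd
            D2 = Xd.T @ (Xd * wd[:, None]) if need_hess else None
            ll += float(np.sum(eta[order[i:j]][dmask]))
            for l in range(m):
                f = l / m
                denom = S0 - f * D0
                ll -= np.log(denom) + c
                z = (S1 - f * D1) / denom
                g -= z
                if need_hess:
                    info += (S2 - f * D2) / denom - np.outer(z, z)
            g += np.sum(Xd, axis=0)
        i = j
    return ll, g, info


def _newton_raphson(objective, theta0, tol, max_iter, what):
    """Maximize via damped Newton; ``objective(theta, need_hess)`` returns
    (value, gradient, information)."""
    theta = theta0.copy()
    ll, g, info = objective(theta, True)
    trace = [ll]
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"{what}: singular information matrix", trace) from exc
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            ll_new, g_new, info_new = objective(cand, True)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(f"{what}: step-halving failed to improve likelihood", trace)
        delta = ll_new - ll
        theta, ll, g, info = cand, ll_new, g_new, info_new
        trace.append(ll)
        if np.max(np.abs(theta)) > 15:
            raise ConvergenceError(
                f"{what}: coefficients diverging (monotone likelihood?)", trace)
        if abs(delta) < tol:
            return theta, ll, g, info, it, trace
    raise ConvergenceError(f"{what}: no convergence in {max_iter} iterations", trace)


# ---------------------------------------------------------------------------
# Fixed-effects Cox model
# ---------------------------------------------------------------------------

class CoxPH:
    """Cox proportional-hazards model with Efron tie handling.

    Parameters
    ----------
    tol : float
        Convergence threshold on the change in log partial likelihood.
    max_iter : int
        Newton-Raphson iteration cap.
    alpha : float
        Two-sided significance level used when flagging coefficients.
    """

    def __init__(self, tol=1e-8, max_iter=50, alpha=0.05):
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha

    def get_params(self, deep=True):
        return {"tol": self.tol, "max_iter": self.max_iter, "alpha": self.alpha}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, X, durations, events, feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        t = np.asarray(durations, dtype=float)
        e = np.asarray(events, dtype=int)
        if np.any(t <= 0):
            raise ValueError("durations must be positive")
        if e.sum() == 0:
            raise ValueError("no events observed; Cox model cannot be fitted")
        sd = X.std(axis=0)
        if np.any(sd == 0):
            bad = list(np.flatnonzero(sd == 0))
            raise DegeneracyError(f"covariate column(s) {bad} have zero variance")
        self.feature_names_ = (list(feature_names) if feature_names is not None
                               else [f"x{i}" for i in range(X.shape[1])])
        order = np.argsort(-t, kind="stable")

        def obj(theta, need_hess):
            return _efron_quantities(theta, X, t, e, order, need_hess)

        beta0 = np.zeros(X.shape[1])
        beta, ll, g, info, n_iter, trace = _newton_raphson(
            obj, beta0, self.tol, self.max_iter, "CoxPH")
        cov = np.linalg.inv(info)
        self.coef_ = beta
        self.loglik_ = ll
        self.score_ = g
        self.information_ = info
        self.covariance_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.z_ = beta / self.se_
        self.p_ = 2.0 * stats.norm.sf(np.abs(self.z_))
        self.hazard_ratios_ = np.exp(beta)
        self.n_iter_ = n_iter
        self.trace_ = trace
        self.n_events_ = int(e.sum())
        return self

    def confidence_intervals(self, alpha=None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        zq = stats.norm.ppf(1 - a / 2)
        return np.column_stack([self.coef_ - zq * self.se_, self.coef_ + zq * self.se_])

    def summary(self) -> pd.DataFrame:
        """Coefficient table: beta, exp(beta), SE, z, p, significance flag."""
        return pd.DataFrame({
            "coef": self.coef_, "exp_coef": self.hazard_ratios_, "se": self.se_,
            "z": self.z_, "p": self.p_, "significant": self.p_ < self.alpha,
        }, index=self.feature_names_)


# ---------------------------------------------------------------------------
# Gaussian-frailty (mixed) Cox model
# ---------------------------------------------------------------------------

class CoxFrailty:
    """Cox model with a Gaussian random intercept per group (seal).

    The penalized partial likelihood
    ``l_p(beta, b) - b'b / (2 sigma_b^2)`` is maximized over (beta, b) by
    Newton-Raphson for fixed ``sigma_b^2``; the variance itself maximizes
    the Laplace approximation to the integrated (marginal) likelihood on a
    log scale with Brent's method.  If the profile optimum collapses below
    ``var_floor`` the model degenerates to the fixed-effects fit with
    ``frailty_variance_ = 0`` and a note in ``notes_``.
    """

    def __init__(self, tol=1e-8, max_iter=50, alpha=0.05,
                 var_bounds=(1e-6, 100.0), var_floor=1e-8):
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha
        self.var_bounds = var_bounds
        self.var_floor = var_floor

    def get_params(self, deep=True):
        return {"tol": self.tol, "max_iter": self.max_iter, "alpha": self.alpha,
                "var_bounds": self.var_bounds, "var_floor": self.var_floor}

    def set_params(self, **p):
        for k, v in p.items():
            setattr(self, k, v)
        return self

    def fit(self, X, durations, events, groups, feature_names=None):
        X = np.asarray(X, dtype=float)
        t = np.asarray(durations, dtype=float)
        e = np.asarray(events, dtype=int)
        groups = np.asarray(groups)
        levels, z_idx = np.unique(groups, return_inverse=True)
        q = len(levels)
        if q < 2:
            raise ValueError("frailty model needs at least two groups")
        n, p = X.shape
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise DegeneracyError(
                f"covariate column(s) {list(np.flatnonzero(sd == 0))} have zero variance")
        Z = np.zeros((n, q))
        Z[np.arange(n), z_idx] = 1.0
        W = np.hstack([X, Z])
        order = np.argsort(-t, kind="stable")
        self.feature_names_ = (list(feature_names) if feature_names is not None
                               else [f"x{i}" for i in range(p)])
        self.group_levels_ = levels

        pen_idx = np.arange(p, p + q)
        theta_warm = np.zeros(p + q)

        def inner_fit(var):
            def obj(theta, need_hess):
                ll, g, info = _efron_quantities(theta, W, t, e, order, need_hess)
                b = theta[pen_idx]
                ll -= 0.5 * float(b @ b) / var
                g = g.copy()
                g[pen_idx] -= b / var
                if info is not None:
                    info = info.copy()
                    info[pen_idx, pen_idx] += 1.0 / var
                return ll, g, info

            return _newton_raphson(obj, theta_warm.copy(), self.tol,
                                   self.max_iter, "CoxFrailty inner")

        def neg_marginal(log_var):
            nonlocal theta_warm
            var = float(np.exp(log_var))
            theta, ll_pen, _, info_pen, _, _ = inner_fit(var)
            theta_warm = theta
            K = info_pen[np.ix_(pen_idx, pen_idx)]
            sign, logdet = np.linalg.slogdet(K)
            if sign <= 0:
                return np.inf
            lm = ll_pen - 0.5 * q * np.log(var) - 0.5 * logdet
            return -lm

        lo, hi = (float(np.log(v)) for v in self.var_bounds)
        res = optimize.minimize_scalar(neg_marginal, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": 1e-4})
        var_hat = float(np.exp(res.x))
        self.notes_ = []
        # collapse test: compare against the boundary sigma^2 -> 0 (fixed fit)
        fixed = CoxPH(tol=self.tol, max_iter=self.max_iter, alpha=self.alpha).fit(
            X, t, e, feature_names=self.feature_names_)
        near_lower = res.x <= lo + 1e-2
        if var_hat < self.var_floor or (near_lower and fixed.loglik_ >= -res.fun - 1e-6):
            self.notes_.append("frailty variance collapsed; returning fixed-effects fit")
            self.frailty_variance_ = 0.0
            self.random_effects_ = pd.Series(np.zeros(q), index=levels)
            for attr in ("coef_", "se_", "z_", "p_", "hazard_ratios_", "covariance_",
                         "information_", "loglik_", "n_iter_", "trace_", "n_events_"):
                setattr(self, attr, getattr(fixed, attr))
            self.marginal_loglik_ = fixed.loglik_
            return self

        theta, ll_pen, g, info_pen, n_iter, trace = inner_fit(var_hat)
        cov = np.linalg.inv(info_pen)
        self.frailty_variance_ = var_hat
        self.coef_ = theta[:p]
        self.random_effects_ = pd.Series(theta[pen_idx], index=levels)
        self.covariance_ = cov[:p, :p]
        self.information_ = info_pen
        self.se_ = np.sqrt(np.diag(self.covariance_))
        self.z_ = self.coef_ / self.se_
        self.p_ = 2.0 * stats.norm.sf(np.abs(self.z_))
        self.hazard_ratios_ = np.exp(self.coef_)
        self.loglik_ = ll_pen
        self.marginal_loglik_ = -res.fun
        self.n_iter_ = n_iter
        self.trace_ = trace
        self.n_events_ = int(e.sum())
        return self

    def confidence_intervals(self, alpha=None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        zq = stats.norm.ppf(1 - a / 2)
        return np.column_stack([self.coef_ - zq * self.se_, self.coef_ + zq * self.se_])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef_, "exp_coef": self.hazard_ratios_, "se": self.se_,
            "z": self.z_, "p": self.p_, "significant": self.p_ < self.alpha,
        }, index=self.feature_names_)


# ---------------------------------------------------------------------------
# Risk-interval front ends
# ---------------------------------------------------------------------------

def pick_reference(intervals: pd.DataFrame) -> str:
    """Jurisdiction with the highest empirical crossing rate
    (events per day at risk), used as the hazard-ratio reference level."""
    g = intervals.groupby("unit")
    rate = g["event"].sum() / (g["t_stop"].sum() - g["t_start"].sum())
    return str(rate.idxmax())


def design_from_intervals(intervals: pd.DataFrame, reference: str | None = None):
    """One-hot jurisdiction design (reference level omitted) plus body weight.

    Jurisdictions in which no crossing was ever observed are excluded (their
    log hazard ratio has no finite maximum-likelihood estimate; dropping
    their intervals is the profile limit of the full fit) with a warning.
    Returns ``(X, durations, events, names, reference, groups)``.
    """
    ev_per_unit = intervals.groupby("unit")["event"].sum()
    dead = sorted(ev_per_unit.index[ev_per_unit == 0])
    if dead:
        logger.warning("unit(s) %s have no observed crossings; their %d interval(s) "
                       "are excluded from the Cox fit", dead,
                       int(intervals["unit"].isin(dead).sum()))
        intervals = intervals[~intervals["unit"].isin(dead)]
    if reference is None:
        reference = pick_reference(intervals)
    units = sorted(u for u in intervals["unit"].unique() if u != reference)
    if not units:
        raise DegeneracyError("need at least two jurisdiction levels")
    cols = [(intervals["unit"] == u).to_numpy(float) for u in units]
    names = [f"unit[{u}]" for u in units]
    has_weight = "weight_kg" in intervals.columns and intervals["weight_kg"].notna().all()
    if has_weight:
        cols.append(intervals["weight_kg"].to_numpy(float))
        names.append("weight_kg")
    X = np.column_stack(cols)
    dur = (intervals["t_stop"] - intervals["t_start"]).to_numpy(float)
    ev = intervals["event"].to_numpy(int)
    return X, dur, ev, names, reference, intervals["seal_id"].to_numpy()


def cox_fixed(intervals: pd.DataFrame, reference: str | None = None, **kwargs) -> CoxPH:
    """Fit the fixed-effects Cox model on risk intervals (jurisdiction + weight)."""
    X, dur, ev, names, ref, _ = design_from_intervals(intervals, reference)
    model = CoxPH(**kwargs).fit(X, dur, ev, feature_names=names)
    model.reference_ = ref
    return model


def cox_frailty(intervals: pd.DataFrame, reference: str | None = None, **kwargs) -> CoxFrailty:
    """Fit the per-seal Gaussian-frailty Cox model on risk intervals."""
    X, dur, ev, names, ref, groups = design_from_intervals(intervals, reference)
    model = CoxFrailty(**kwargs).fit(X, dur, ev, groups, feature_names=names)
    model.reference_ = ref
    return model
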