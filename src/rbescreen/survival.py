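"""Outcome analysis for remission cohorts with competing risks.

A subject enters the cohort at first complete remission and is followed until
first relapse, death in remission, or censoring — exactly one of the event
codes ``"relapse"``, ``"death"``, ``"censored"``, with time measured in
months.  The module provides:

* relapse-free survival by Kaplan–Meier (by default both relapse and death in
  remission count as RFS events; configurable via ``events=``) with
  Greenwood/log-log confidence bands, and the log-rank test;
* the cumulative incidence of relapse treating death in remission as a
  competing risk (Aalen–Johansen estimator), with a Gray-type permutation
  test for comparing cumulative incidence between groups;
* Cox proportional-hazards regression on the cause-specific hazard
  (competing deaths censored at their time), fit by Newton–Raphson with the
  Efron or Breslow tie correction, plus sequential backward elimination of
  covariates with Wald P > 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm

from .errors import ConvergenceError, DataError

__all__ = [
    "EVENT_RELAPSE",
    "EVENT_DEATH",
    "EVENT_CENSORED",
    "SurvFit",
    "CIFFit",
    "CoxFit",
    "EliminationResult",
    "PointEstimate",
    "km_fit",
    "logrank",
    "cif_fit",
    "gray_test",
    "cox_fit",
    "backward_eliminate",
    "point_estimate_at",
]

EVENT_RELAPSE = "relapse"
EVENT_DEATH = "death"
EVENT_CENSORED = "censored"
EVENT_CODES = (EVENT_RELAPSE, EVENT_DEATH, EVENT_CENSORED)

RFS_EVENTS = (EVENT_RELAPSE, EVENT_DEATH)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise DataError("empty cohort")
    for col in ("time", "event"):
        if col not in records.columns:
            raise DataError(f"records lack required column {col!r}")
    t = records["time"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t <= 0).any():
        raise DataError("times must be finite and > 0")
    bad = set(records["event"]) - set(EVENT_CODES)
    if bad:
        raise DataError(f"unknown event codes: {sorted(bad)}; expected {EVENT_CODES}")
    return records


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank (via lifelines)
# ---------------------------------------------------------------------------


@dataclass
class SurvFit:
    """Kaplan-Meier estimate with Greenwood (log-log) confidence band."""

    kmf: KaplanMeierFitter
    events_counted: tuple[str, ...]
    n: int
    n_events: int

    @property
    def survival(self) -> pd.Series:
        return self.kmf.survival_function_.iloc[:, 0]

    @property
    def confidence(self) -> pd.DataFrame:
        ci = self.kmf.confidence_interval_
        return ci.set_axis(["lower", "upper"], axis=1)

    def predict(self, t: float) -> float:
        return float(self.kmf.predict(t))


def km_fit(
    records: pd.DataFrame,
    events: tuple[str, ...] = RFS_EVENTS,
    label: str = "S(t)",
) -> SurvFit:
    """Product-limit estimate of event-free survival.

    ``events`` lists the codes that count as events (default: relapse or
    death in remission, i.e. relapse-free survival); everything else is
    censored at its observed time.
    """
    records = _check_records(records)
    observed = records["event"].isin(events).to_numpy()
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"].to_numpy(dtype=float), observed, label=label)
    return SurvFit(kmf=kmf, events_counted=tuple(events), n=len(records), n_events=int(observed.sum()))


def logrank(
    records: pd.DataFrame,
    group: str,
    events: tuple[str, ...] = RFS_EVENTS,
) -> tuple[float, float]:
    """K-sample log-rank test of event-free survival across ``group``.

    Returns ``(chi_square, p_value)``.
    """
    records = _check_records(records)
    if group not in records.columns:
        raise DataError(f"no column {group!r}")
    counts = records[group].value_counts()
    if len(counts) < 2:
        raise DataError("log-rank needs at least 2 groups")
    observed = records["event"].isin(events).to_numpy().astype(int)
    if observed.sum() == 0:
        raise DataError("log-rank needs at least one event")
    res = multivariate_logrank_test(
        records["time"].to_numpy(dtype=float), records[group].to_numpy(), observed
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence under competing risks
# ---------------------------------------------------------------------------


@dataclass
class CIFFit:
    """Aalen-Johansen cumulative incidence functions for relapse and death.

    ``times`` are the distinct event times; the step functions are
    right-continuous, starting at 0.  ``event_free`` is the all-cause
    Kaplan-Meier, so CIF_relapse + CIF_death + event_free = 1 at every step.
    """

    times: np.ndarray
    cif_relapse: np.ndarray
    cif_death: np.ndarray
    event_free: np.ndarray
    n: int
    records: pd.DataFrame = field(repr=False)

    def _step(self, values: np.ndarray, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(values[idx]) if idx >= 0 else (1.0 if values is self.event_free else 0.0)

    def predict(self, t: float, cause: str = EVENT_RELAPSE) -> float:
        arr = {EVENT_RELAPSE: self.cif_relapse, EVENT_DEATH: self.cif_death}[cause]
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(arr[idx]) if idx >= 0 else 0.0


def cif_fit(records: pd.DataFrame) -> CIFFit:
    """Aalen-Johansen estimator of the cause-specific cumulative incidences.

    CIF_cause(t) = sum over event times t_i <= t of S(t_i-) * d_cause(t_i) / n(t_i)
    where S is the all-cause event-free Kaplan-Meier and n the risk set size.
    With no competing deaths this reduces exactly to 1 - KM(relapse).
    """
    records = _check_records(records)
    t = records["time"].to_numpy(dtype=float)
    ev = records["event"].to_numpy()
    order = np.argsort(t, kind="mergesort")
    t, ev = t[order], ev[order]
    n_total = len(t)

    event_times = np.unique(t[ev != EVENT_CENSORED])
    s_minus = 1.0
    cif_r, cif_d, s_all = [], [], []
    cr = cd = 0.0
    for tau in event_times:
        at_risk = n_total - np.searchsorted(t, tau, side="left")
        here = t == tau
        d_r = int(((ev == EVENT_RELAPSE) & here).sum())
        d_d = int(((ev == EVENT_DEATH) & here).sum())
        cr += s_minus * d_r / at_risk
        cd += s_minus * d_d / at_risk
        s_minus *= 1.0 - (d_r + d_d) / at_risk
        cif_r.append(cr)
        cif_d.append(cd)
        s_all.append(s_minus)
    return CIFFit(
        times=event_times,
        cif_relapse=np.asarray(cif_r),
        cif_death=np.asarray(cif_d),
        event_free=np.asarray(s_all),
        n=n_total,
        records=records.reset_index(drop=True),
    )


def _censoring_km_left(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pooled Kaplan-Meier of the censoring distribution, for left limits G(t-)."""
    t = records["time"].to_numpy(dtype=float)
    cens = (records["event"] == EVENT_CENSORED).to_numpy()
    kmf = KaplanMeierFitter()
    kmf.fit(t, cens)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def _g_at(times: np.ndarray, values: np.ndarray, query: np.ndarray, left: bool) -> np.ndarray:
    side = "left" if left else "right"
    idx = np.searchsorted(times, query, side=side) - 1
    out = np.ones_like(query, dtype=float)
    ok = idx >= 0
    out[ok] = values[idx[ok]]
    return out


def gray_test(
    records: pd.DataFrame,
    group: str,
    cause: str = EVENT_RELAPSE,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Gray-type test for equality of cumulative incidence across groups.

    The score compares, at every time a ``cause`` event occurs, the observed
    cause-specific failures in each group with those expected from the pooled
    subdistribution hazard.  The risk sets are the subdistribution ones:
    subjects who failed from the competing cause remain "at risk", weighted by
    the pooled censoring Kaplan-Meier G(t-)/G(t_i) (inverse-probability-of-
    censoring weighting), as in the Fine-Gray construction.  The p-value is
    obtained by permuting group labels (``n_permutations`` draws, seeded), so
    it is exact under the exchangeable null of equal cumulative incidence and
    equal censoring.  Returns ``(statistic, p_value)`` where the statistic is
    the sum over groups of the squared scores.
    """
    records = _check_records(records)
    if group not in records.columns:
        raise DataError(f"no column {group!r}")
    labels = records[group].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DataError("gray_test needs at least 2 groups")
    t = records["time"].to_numpy(dtype=float)
    ev = records["event"].to_numpy()
    if (ev == cause).sum() == 0:
        raise DataError(f"no {cause!r} events")

    taus = np.unique(t[ev == cause])  # cause event times
    n, k = len(t), len(taus)

    g_times, g_vals = _censoring_km_left(records)
    g_tau_minus = _g_at(g_times, g_vals, taus, left=True)  # G(tau-)
    g_at_t = _g_at(g_times, g_vals, t, left=False)  # G(t_i)

    # subdistribution at-risk weight matrix W[i, j] at time taus[j]
    still_at_risk = t[:, None] >= taus[None, :]
    failed_other = ((ev != cause) & (ev != EVENT_CENSORED))[:, None] & (t[:, None] < taus[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        ipcw = np.where(g_at_t[:, None] > 0, g_tau_minus[None, :] / g_at_t[:, None], 0.0)
    W = np.where(still_at_risk, 1.0, np.where(failed_other, ipcw, 0.0))

    # cause-failure indicator matrix D[i, j]
    D = ((ev == cause)[:, None]) & (t[:, None] == taus[None, :])
    D = D.astype(float)
    d_tot = D.sum(axis=0)
    y_tot = W.sum(axis=0)

    def statistic(label_matrix: np.ndarray) -> np.ndarray:
        # label_matrix: (reps, n) of labels; returns (reps,) statistics
        stat = np.zeros(label_matrix.shape[0])
        for g in uniq:
            u = (label_matrix == g).astype(float)
            z = (u @ D - (u @ W) * (d_tot / y_tot)).sum(axis=1)
            stat += z**2
        return stat

    obs = float(statistic(labels[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_stats = statistic(labels[perms])
    p = (1.0 + (perm_stats >= obs - 1e-12).sum()) / (1.0 + n_permutations)
    return obs, float(p)


# ---------------------------------------------------------------------------
# Cox proportional hazards (cause-specific), Newton-Raphson
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Cox model fit: per-covariate coefficients, hazard ratios, Wald tests."""

    summary: pd.DataFrame  # index: covariate; coef, se, hr, hr_lower, hr_upper, z, p
    loglik: float
    loglik_null: float
    converged: bool
    n: int
    n_events: int
    ties: str
    events_counted: tuple[str, ...]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["hr"]


def _cox_quantities(
    beta: np.ndarray,
    X: np.ndarray,
    first_risk_idx: np.ndarray,
    event_rows: np.ndarray,
    tie_groups: list[np.ndarray],
    ties: str,
):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Rows are sorted by ascending time.  ``first_risk_idx[g]`` is the first
    row of the risk set for tie group g; ``tie_groups[g]`` are the event rows
    sharing that time.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # overflow guard; cancels in the partial likelihood
    theta = np.exp(eta)
    xt = X * theta[:, None]
    xxt = X[:, :, None] * X[:, None, :] * theta[:, None, None]
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum(xt[::-1], axis=0)[::-1]
    s2 = np.cumsum(xxt[::-1], axis=0)[::-1]

    ll = float(eta[event_rows].sum())
    grad = X[event_rows].sum(axis=0)
    hess = np.zeros((p, p))

    sizes = np.array([len(rows) for rows in tie_groups])
    S0g = s0[first_risk_idx]
    S1g = s1[first_risk_idx]
    S2g = s2[first_risk_idx]
    plain = sizes == 1 if ties == "efron" else np.ones_like(sizes, dtype=bool)
    if plain.any():  # untied times (and all times under Breslow): vectorized
        d = sizes[plain].astype(float)
        S0, S1, S2 = S0g[plain], S1g[plain], S2g[plain]
        ll -= float((d * np.log(S0)).sum())
        m1 = S1 / S0[:, None]
        grad -= (d[:, None] * m1).sum(axis=0)
        hess += (
            d[:, None, None] * (S2 / S0[:, None, None] - m1[:, :, None] * m1[:, None, :])
        ).sum(axis=0)
    if ties == "efron":
        for g in np.flatnonzero(~plain):  # Efron correction for d tied events
            rows = tie_groups[g]
            d = len(rows)
            s0t = theta[rows].sum()
            s1t = xt[rows].sum(axis=0)
            s2t = xxt[rows].sum(axis=0)
            for l in range(d):
                f = l / d
                denom = S0g[g] - f * s0t
                num1 = S1g[g] - f * s1t
                num2 = S2g[g] - f * s2t
                ll -= np.log(denom)
                grad -= num1 / denom
                m1 = num1 / denom
                hess += num2 / denom - np.outer(m1, m1)
    return ll, grad, hess


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    events: tuple[str, ...] = (EVENT_RELAPSE,),
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards fit on the cause-specific hazard.

    ``events`` lists the codes treated as events; competing events are
    censored at their occurrence time (cause-specific hazard).  The partial
    likelihood (Efron tie correction by default; ``ties="breslow"``
    available) is maximized by Newton-Raphson with step halving, tolerance
    ``tol`` on the coefficient update, at most ``max_iter`` iterations.
    Wald confidence intervals and p-values come from the inverse observed
    information.

    Raises :class:`DataError` for constant covariates (named) or no events;
    non-convergence / monotone likelihood (perfect separation) raises
    :class:`ConvergenceError`.
    """
    records = _check_records(records)
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise DataError(f"missing covariate columns: {missing}")
    X = records[list(covariates)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DataError("non-finite covariate values")
    for j, c in enumerate(covariates):
        if X[:, j].std() == 0:
            raise DataError(f"covariate {c!r} is constant")
    delta = records["event"].isin(events).to_numpy()
    if delta.sum() == 0:
        raise DataError("no events of the requested type")
    t = records["time"].to_numpy(dtype=float)

    order = np.argsort(t, kind="mergesort")
    t, X, delta = t[order], X[order], delta[order]
    xbar = X.mean(axis=0)
    Xc = X - xbar  # centering: improves conditioning, leaves beta unchanged

    event_rows = np.flatnonzero(delta)
    ev_times, first_of_time = np.unique(t[event_rows], return_index=True)
    tie_groups = [event_rows[t[event_rows] == tau] for tau in ev_times]
    first_risk_idx = np.searchsorted(t, ev_times, side="left")

    p = Xc.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_quantities(beta, Xc, first_risk_idx, event_rows, tie_groups, ties)
    ll_null = ll
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving if the likelihood does not improve
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _cox_quantities(
                cand, Xc, first_risk_idx, event_rows, tie_groups, ties
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(scale * step).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Cox fit did not converge within the iteration budget", stacklevel=2)
    if np.abs(beta).max() > 30:
        raise ConvergenceError(
            "monotone partial likelihood (perfect separation?): |beta| diverged"
        )

    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * norm.sf(np.abs(z))
    zc = norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_lower": np.exp(beta - zc * se),
            "hr_upper": np.exp(beta + zc * se),
            "z": z,
            "p": pvals,
        },
        index=pd.Index(list(covariates), name="covariate"),
    )
    return CoxFit(
        summary=summary,
        loglik=ll,
        loglik_null=ll_null,
        converged=converged,
        n=len(t),
        n_events=int(delta.sum()),
        ties=ties,
        events_counted=tuple(events),
    )


@dataclass
class EliminationResult:
    """Final model after backward elimination plus the removal trace."""

    final: CoxFit | None  # None when every covariate was eliminated
    trace: list[dict]  # one entry per removal: covariate, p, step
    kept: list[str]


def backward_eliminate(
    records: pd.DataFrame,
    covariates: list[str],
    keep_alpha: float = 0.1,
    events: tuple[str, ...] = (EVENT_RELAPSE,),
    **cox_kwargs,
) -> EliminationResult:
    """Sequential backward elimination of Cox covariates with Wald P > ``keep_alpha``.

    At each step the model is refit and the single covariate with the largest
    p-value among those exceeding ``keep_alpha`` is removed, until every
    remaining covariate has p <= ``keep_alpha`` (or none remain).
    """
    if not covariates:
        raise DataError("no covariates supplied")
    current = list(covariates)
    trace: list[dict] = []
    fit: CoxFit | None = None
    step = 0
    while current:
        fit = cox_fit(records, current, events=events, **cox_kwargs)
        pvals = fit.summary["p"]
        worst = pvals.idxmax()
        if pvals[worst] <= keep_alpha:
            break
        step += 1
        trace.append({"covariate": worst, "p": float(pvals[worst]), "step": step})
        current.remove(worst)
        fit = None
    if current and fit is None:  # pragma: no cover - defensive
        fit = cox_fit(records, current, events=events, **cox_kwargs)
    return EliminationResult(final=fit if current else None, trace=trace, kept=current)


# ---------------------------------------------------------------------------
# Point estimates at a landmark time
# ---------------------------------------------------------------------------


@dataclass
class PointEstimate:
    value: float
    lower: float
    upper: float
    t: float


def point_estimate_at(
    fit: SurvFit | CIFFit,
    t: float = 60.0,
    cause: str = EVENT_RELAPSE,
    n_boot: int = 500,
    seed: int = 0,
) -> PointEstimate:
    """Step-function value at landmark time ``t`` (default 60 months) with CI.

    For a Kaplan-Meier fit the Greenwood/log-log band is read off at ``t``;
    for a cumulative-incidence fit the CI is a seeded percentile bootstrap
    over subjects (``n_boot`` resamples).  A ``t`` beyond the last observed
    time carries the last value forward with a warning.
    """
    if isinstance(fit, SurvFit):
        last = float(fit.kmf.timeline.max())
        if t > last:
            warnings.warn(f"t={t} beyond last observed time {last}; carrying forward", stacklevel=2)
        value = fit.predict(t)
        ci = fit.confidence
        idx = np.searchsorted(ci.index.to_numpy(dtype=float), t, side="right") - 1
        if idx >= 0:
            lower, upper = float(ci.iloc[idx, 0]), float(ci.iloc[idx, 1])
        else:
            lower = upper = 1.0
        return PointEstimate(value=value, lower=lower, upper=upper, t=t)

    if isinstance(fit, CIFFit):
        if len(fit.times) and t > fit.times.max():
            warnings.warn(
                f"t={t} beyond last event time {fit.times.max()}; carrying forward", stacklevel=2
            )
        value = fit.predict(t, cause=cause)
        rng = np.random.default_rng(seed)
        n = len(fit.records)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            sample = fit.records.iloc[rng.integers(0, n, n)]
            try:
                boots[b] = cif_fit(sample).predict(t, cause=cause)
            except DataError:
                boots[b] = 0.0
        lower, upper = np.percentile(boots, [2.5, 97.5])
        return PointEstimate(value=value, lower=float(lower), upper=float(upper), t=t)

    raise TypeError(f"unsupported fit type {type(fit).__name__}")
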