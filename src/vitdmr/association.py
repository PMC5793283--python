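"""First-stage linear calibration and Cox proportional-hazards fits.

The first stage (25OHD on the score) is ordinary least squares via
statsmodels.  The Cox model is fitted here by Newton-Raphson on the
partial likelihood with Breslow handling of ties (Efron available behind
a flag), standard errors from the inverse observed information, plus a
Schoenfeld-residual check of the proportionality assumption and simple
incidence-rate tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FirstStageFit",
    "CoxFit",
    "RateRow",
    "fit_linear",
    "fit_cox",
    "cox_score_test",
    "check_proportionality",
    "rate_table",
    "Z975",
]

logger = logging.getLogger(__name__)

#: two-sided 97.5% normal quantile used for every 95% CI in the package
Z975 = 1.959964


@dataclass
class FirstStageFit:
    """OLS fit of 25OHD on the instrument (exposure-only R2/F).

    ``f_stat`` is the single-predictor F, equal to r2 (n-2) / (1 - r2).
    When covariates are supplied the adjusted slope/SE are carried in
    ``adjusted_slope``/``adjusted_slope_se`` (R2 and F still refer to the
    exposure-only model).
    """

    slope: float
    slope_se: float
    intercept: float
    r2: float
    f_stat: float
    n: int
    adjusted_slope: float | None = None
    adjusted_slope_se: float | None = None


@dataclass
class CoxFit:
    """A fitted Cox model; headline fields refer to the exposure term."""

    coef: float
    coef_se: float
    hr: float
    ci95: tuple[float, float]
    p: float
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)
    coefs: np.ndarray | None = None
    ses: np.ndarray | None = None
    ties: str = "breslow"

    def term(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.coefs[i]), float(self.ses[i])


@dataclass(frozen=True)
class RateRow:
    """One row of an incidence-rate table."""

    group: str
    cases: int
    n: int
    person_years: float
    rate_per_1000: float


def fit_linear(
    y: Sequence[float],
    x: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> FirstStageFit:
    """OLS of ``y`` (25OHD, nmol/L) on ``x`` (the score).

    Missing values are removed listwise (count logged).  R-squared and
    the F statistic always describe the exposure-only regression; the
    covariate-adjusted slope, when requested, is reported separately.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
    keep = ~(np.isnan(y) | np.isnan(x))
    if cov is not None:
        keep &= ~cov.isna().any(axis=1).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("fit_linear: dropped %d rows with missing values", dropped)
    y, x = y[keep], x[keep]
    n = len(y)
    n_pred = 1 + (0 if cov is None else cov.shape[1])
    if n <= n_pred + 1:
        raise ValueError(f"too few complete observations (n={n})")
    if np.ptp(x) == 0:
        raise ValueError("exposure column is constant (zero variance)")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    fit = FirstStageFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        n=n,
    )
    if cov is not None:
        X = sm.add_constant(np.column_stack([x, cov.loc[keep].to_numpy(float)]))
        adj = sm.OLS(y, X).fit()
        fit.adjusted_slope = float(adj.params[1])
        fit.adjusted_slope_se = float(adj.bse[1])
    return fit


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery


def _prepare(times, events, exposure, covariates, name, cov_names):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    exposure = np.asarray(exposure, dtype=float)
    cols = [exposure]
    names = [name]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        if cov_names is None:
            cov_names = [str(c) for c in cov.columns]
        cols.extend(cov.to_numpy(dtype=float).T)
        names.extend(cov_names)
    X = np.column_stack(cols)
    keep = ~(np.isnan(times) | np.isnan(X).any(axis=1))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("fit_cox: dropped %d rows with missing values", dropped)
    times, events, X = times[keep], events[keep].astype(int), X[keep]
    if (times <= 0).any():
        raise ValueError("all follow-up times must be > 0")
    if events.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    # centering columns leaves the partial likelihood invariant but keeps
    # exp(eta) well conditioned
    center = X.mean(axis=0)
    return times, events, X - center, names


def _loglik_parts(beta, times, events, X, ties):
    """Breslow/Efron partial log-likelihood, score vector and observed
    information, computed from suffix sums over subjects sorted by time."""
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    n, p = Xs.shape
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * Xs
    wXX = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
    # suffix sums: S*(i) aggregates subjects with time >= t_i
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    # event groups by distinct event time
    ev_idx = np.flatnonzero(e == 1)
    ev_t = t[ev_idx]
    group_starts = np.flatnonzero(np.concatenate([[True], np.diff(ev_t) > 0]))
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    for g, s in enumerate(group_starts):
        stop = group_starts[g + 1] if g + 1 < len(group_starts) else len(ev_idx)
        members = ev_idx[s:stop]
        d = len(members)
        tj = ev_t[s]
        first = np.searchsorted(t, tj, side="left")
        s_j = Xs[members].sum(axis=0)
        ll += s_j @ beta
        if ties == "breslow" or d == 1:
            s0, s1, s2 = S0[first], S1[first], S2[first]
            xbar = s1 / s0
            ll -= d * np.log(s0)
            U += s_j - d * xbar
            I += d * (s2 / s0 - np.outer(xbar, xbar))
        else:  # efron
            w_t = w[members].sum()
            s1_t = wX[members].sum(axis=0)
            s2_t = wXX[members].sum(axis=0)
            for l in range(d):
                f = l / d
                s0 = S0[first] - f * w_t
                s1 = S1[first] - f * s1_t
                s2 = S2[first] - f * s2_t
                xbar = s1 / s0
                ll -= np.log(s0)
                U += s_j / d - xbar
                I += s2 / s0 - np.outer(xbar, xbar)
    return ll, U, I


def fit_cox(
    times: Sequence[float],
    events: Sequence[int],
    exposure: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    ties: str = "breslow",
    exposure_name: str = "exposure",
    covariate_names: list[str] | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson from beta = 0.

    Ties are handled by the Breslow approximation by default (``ties=
    "efron"`` for Efron's correction, which agrees with Breslow on
    tie-free data).  Newton steps are halved whenever the partial
    log-likelihood would decrease; convergence is declared when the
    largest score component falls below ``score_tol`` or the
    log-likelihood improvement below ``loglik_tol``.  A fit hitting
    ``max_iter`` (e.g. monotone likelihood under perfect separation) is
    returned with ``converged=False`` rather than raising.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    times, events, X, names = _prepare(
        times, events, exposure, covariates, exposure_name, covariate_names
    )
    n, p = X.shape
    beta = np.zeros(p)
    ll, U, I = _loglik_parts(beta, times, events, X, ties)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(I, U, rcond=None)[0]
        scale = 1.0
        for _ in range(30):  # step-halving on loglik decrease
            cand = beta + scale * step
            ll_new, U_new, I_new = _loglik_parts(cand, times, events, X, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        improvement = ll_new - ll
        beta, ll, U, I = cand, ll_new, U_new, I_new
        if np.max(np.abs(U)) < score_tol or abs(improvement) < loglik_tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(I)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(p, np.nan)
        converged = False
    # monotone-likelihood guard: a coefficient drifting to a huge per-SD
    # log hazard means the likelihood has no interior maximum (perfect
    # separation); the loglik plateau alone would masquerade as converged
    if np.any(np.abs(beta) * X.std(axis=0) > 10.0):
        converged = False
    coef, se = float(beta[0]), float(ses[0])
    z = coef / se if se > 0 else np.nan
    return CoxFit(
        coef=coef,
        coef_se=se,
        hr=float(np.exp(coef)),
        ci95=(float(np.exp(coef - Z975 * se)), float(np.exp(coef + Z975 * se))),
        p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        loglik=float(ll),
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        n_iter=n_iter,
        names=names,
        coefs=beta.copy(),
        ses=ses.copy(),
        ties=ties,
    )


def cox_score_test(
    times: Sequence[float], events: Sequence[int], exposure: Sequence[float]
) -> tuple[float, float]:
    """Score (Rao) test of beta = 0 for a single exposure.

    For a binary exposure with no tied event times this statistic equals
    the logrank chi-square.  Returns ``(chi2, p)`` on 1 df.
    """
    times, events, X, _ = _prepare(times, events, exposure, None, "x", None)
    _, U, I = _loglik_parts(np.zeros(1), times, events, X, "breslow")
    chi2 = float(U[0] ** 2 / I[0, 0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def check_proportionality(
    fit: CoxFit,
    times: Sequence[float],
    events: Sequence[int],
    exposure: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict[str, float]:
    """Schoenfeld-residual test of the proportional-hazards assumption.

    Residuals ``x_i - xbar(t_i)`` are computed at each event under the
    fitted coefficients; per term, the test correlates the residuals with
    the rank of the event time and refers ``d * rho^2`` to chi-square on
    1 df.  With fewer than 3 events the test is undefined (NaN).
    """
    times, events, X, names = _prepare(
        times, events, exposure, covariates, fit.names[0],
        fit.names[1:] if len(fit.names) > 1 else None,
    )
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    w = np.exp(np.clip(Xs @ fit.coefs, -500, 500))
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    ev = np.flatnonzero(e == 1)
    out: dict[str, float] = {}
    if len(ev) < 3:
        return {name: float("nan") for name in names}
    first = np.searchsorted(t, t[ev], side="left")
    resid = Xs[ev] - S1[first] / S0[first][:, None]
    ranks = stats.rankdata(t[ev])
    for j, name in enumerate(names):
        r = resid[:, j]
        if np.std(r) == 0 or np.std(ranks) == 0:
            out[name] = float("nan")
            continue
        rho = float(np.corrcoef(r, ranks)[0, 1])
        chi2 = len(ev) * rho**2
        out[name] = float(stats.chi2.sf(chi2, df=1))
    return out


def jackknife_slope_se(y: Sequence[float], x: Sequence[float]) -> float:
    """Delete-one jackknife SE of the simple-regression slope.

    Offered as an alternative to the model-based OLS slope SE for the
    first stage; on well-behaved data the two agree closely.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 3:
        raise ValueError("jackknife needs at least 3 complete observations")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("exposure column is constant (zero variance)")
    slope = (xc @ y) / sxx
    resid = y - y.mean() - slope * xc
    h = 1.0 / n + xc**2 / sxx
    # closed-form leave-one-out slope change for simple OLS
    loo = slope - xc * resid / ((1.0 - h) * sxx)
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))


def rate_table(
    groups: Sequence[str],
    cases: Sequence[int],
    person_years: Sequence[float],
    n: Sequence[int] | None = None,
) -> list[RateRow]:
    """Incidence rates per 1000 person-years, one row per group."""
    rows = []
    if n is None:
        n = cases
    for g, c, py, ni in zip(groups, cases, person_years, n):
        if c < 0 or ni < 0:
            raise ValueError("negative counts")
        if py <= 0:
            raise ValueError(f"group {g!r}: person_years must be > 0")
        rows.append(
            RateRow(
                group=str(g),
                cases=int(c),
                n=int(ni),
                person_years=float(py),
                rate_per_1000=round(1000.0 * c / py, 2),
            )
        )
    return rows
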