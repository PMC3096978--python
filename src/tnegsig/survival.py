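"""Survival primitives: Kaplan-Meier, log-rank, Cox proportional hazards.

Multivariate Cox fits and k-group log-rank tests delegate to lifelines.
Two hot paths are implemented directly on NumPy because the discovery
screens need them at gene-matrix scale:

* :func:`cox_univariate_batch` -- Newton-Raphson maximisation of the Cox
  partial likelihood for thousands of single covariates simultaneously,
  with Efron or Breslow tie handling.
* :func:`logrank_grid` -- the standard (unweighted) two-group log-rank
  chi-square evaluated for many candidate dichotomisations at once,
  used by the cut-point search.

Both are cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------
@dataclass
class SurvivalFit:
    """Cox model fit: log-hazard coefficients with Wald inference.

    ``hr = exp(coefficient)`` and ``ci95 = exp(coefficient +/- 1.96 se)``
    on the hazard-ratio scale.
    """

    coefficients: pd.Series
    se: pd.Series
    wald_p: pd.Series
    hr: pd.Series
    ci95: pd.DataFrame  # columns: lower, upper
    loglik: float
    n_events: int
    converged: bool = True
    flags: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "se": self.se.to_dict(),
            "wald_p": self.wald_p.to_dict(),
            "hr": self.hr.to_dict(),
            "ci95": {
                k: (float(self.ci95.loc[k, "lower"]), float(self.ci95.loc[k, "upper"]))
                for k in self.ci95.index
            },
            "loglik": self.loglik,
            "n_events": self.n_events,
            "converged": self.converged,
            "flags": self.flags,
        }


@dataclass
class BatchCoxResult:
    """Per-feature univariate Cox results from the vectorised solver."""

    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: np.ndarray  # bool per feature
    constant: np.ndarray  # bool per feature (flagged, coef 0, p 1)


@dataclass
class KMResult:
    """Kaplan-Meier curves per group plus the log-rank comparison.

    ``curves`` maps group label -> DataFrame with columns
    (time, survival, at_risk); survival starts at 1 and is
    non-increasing.  ``logrank_chi2``/``logrank_p`` are ``None`` when
    the test was skipped (single group, or a group without events).
    """

    curves: dict[object, pd.DataFrame]
    logrank_chi2: float | None
    logrank_p: float | None


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------
def km_estimate(times, events, groups=None) -> KMResult:
    """Product-limit survival estimate per group with a log-rank test.

    The test is skipped (with a warning) when fewer than two groups are
    present or any group has zero events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if any((groups == g).sum() == 0 for g in labels):
        raise ValueError("empty group")

    curves: dict[object, pd.DataFrame] = {}
    for g in labels:
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves[g] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": tab["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)

    chi2 = p = None
    if len(labels) >= 2:
        if all(events[groups == g].sum() > 0 for g in labels):
            chi2, p = logrank_test(times, events, groups)
        else:
            warnings.warn("log-rank skipped: a group has zero events")
    return KMResult(curves=curves, logrank_chi2=chi2, logrank_p=p)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Standard (unweighted) k-group log-rank test.

    Returns the chi-square statistic (k-1 df) and its P value.
    """
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


def logrank_grid(times, events, membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank chi-square for many groupings at once.

    Parameters
    ----------
    membership
        Boolean array (n_samples, n_groupings); column j defines the
        "group 1" indicator of grouping j.  Degenerate groupings (empty
        group, zero log-rank variance) get chi2 0 / p 1.

    Returns
    -------
    (chi2, p) arrays of length n_groupings.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    membership = np.asarray(membership, dtype=float)
    if membership.ndim == 1:
        membership = membership[:, None]
    n, m = membership.shape

    order = np.argsort(times, kind="stable")
    t = times[order]
    d = events[order]
    mem = membership[order]

    uniq, start = np.unique(t, return_index=True)
    # at-risk counts at each unique time = suffix counts
    rev_n = np.arange(n, 0, -1, dtype=float)  # at-risk count if cut at index
    n_risk = rev_n[start]  # scalar per unique time
    # at-risk in group 1 per grouping: suffix sums of membership
    suffix = np.cumsum(mem[::-1], axis=0)[::-1]
    n1_risk = suffix[start]  # (G, m)
    # deaths per unique time
    d_tot = np.add.reduceat(d.astype(float), start)
    d1 = np.add.reduceat(mem * d[:, None], start, axis=0)  # (G, m)

    ev = d_tot > 0
    d_tot = d_tot[ev]
    n_risk = n_risk[ev]
    n1 = n1_risk[ev]
    d1 = d1[ev]

    frac = n1 / n_risk[:, None]
    O1 = d1.sum(axis=0)
    E1 = (d_tot[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = (
            d_tot[:, None]
            * frac
            * (1.0 - frac)
            * ((n_risk - d_tot) / np.maximum(n_risk - 1.0, 1.0))[:, None]
        )
    V = vterm.sum(axis=0)
    chi2 = np.zeros(m)
    ok = V > 0
    chi2[ok] = (O1[ok] - E1[ok]) ** 2 / V[ok]
    p = stats.chi2.sf(chi2, df=1)
    p[~ok] = 1.0
    return chi2, p


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------
def cox_fit(
    times,
    events,
    covariates: pd.DataFrame,
    ridge: float = 0.0,
) -> SurvivalFit:
    """Multivariate Cox PH fit (Efron ties) with Wald inference.

    Constant covariates are flagged and reported with coefficient 0 and
    P 1 rather than aborting the fit.  Non-convergence (monotone
    likelihood / complete separation) yields a flagged fit from a
    lightly ridge-stabilised retry instead of an exception.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("cox_fit requires at least one event")
    covariates = pd.DataFrame(covariates)
    if not np.all(np.isfinite(covariates.to_numpy(dtype=float))):
        raise ValueError("covariates must be finite")

    flags: dict[str, str] = {}
    const = covariates.columns[covariates.nunique() <= 1]
    for c in const:
        flags[str(c)] = "constant covariate"
    active = [c for c in covariates.columns if c not in set(const)]

    names = [str(c) for c in covariates.columns]
    coef = pd.Series(0.0, index=names)
    se = pd.Series(np.nan, index=names)
    wald_p = pd.Series(1.0, index=names)
    loglik = float("nan")
    converged = True

    if active:
        df = covariates[active].copy()
        df.columns = [str(c) for c in df.columns]
        df["_T"] = times
        df["_E"] = events
        cph = CoxPHFitter(penalizer=ridge)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_T", event_col="_E")
        except ConvergenceError as err:
            converged = False
            flags["__fit__"] = f"non-convergence, ridge-stabilised retry: {err}"
            cph = CoxPHFitter(penalizer=max(ridge, 0.1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_T", event_col="_E")
        for c in cph.params_.index:
            coef[c] = float(cph.params_[c])
            se[c] = float(cph.standard_errors_[c])
            wald_p[c] = float(
                2.0 * stats.norm.sf(abs(coef[c] / se[c])) if se[c] > 0 else 1.0
            )
        loglik = float(cph.log_likelihood_)

    hr = np.exp(coef)
    ci = pd.DataFrame(
        {
            "lower": np.exp(coef - 1.96 * se),
            "upper": np.exp(coef + 1.96 * se),
        },
        index=names,
    )
    return SurvivalFit(
        coefficients=coef,
        se=se,
        wald_p=wald_p,
        hr=hr,
        ci95=ci,
        loglik=loglik,
        n_events=int(events.sum()),
        converged=converged,
        flags=flags,
    )


def _risk_set_layout(times: np.ndarray, events: np.ndarray):
    """Precompute sort order and tie-group indexing for the batch solver."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    d = events[order].astype(bool)
    uniq, start = np.unique(t, return_index=True)
    # map each row to its unique-time group
    grp_of_row = np.searchsorted(uniq, t)
    death_rows = np.flatnonzero(d)
    death_grp = grp_of_row[death_rows]
    # tie rank l and group death count d_g per death row
    eg, eg_start, d_g = np.unique(death_grp, return_index=True, return_counts=True)
    tie_rank = np.arange(len(death_rows)) - eg_start[np.searchsorted(eg, death_grp)]
    d_of_row = d_g[np.searchsorted(eg, death_grp)]
    return {
        "order": order,
        "start": start,  # first sorted row of each unique time
        "death_rows": death_rows,  # sorted-row indices of events
        "death_grp_pos": np.searchsorted(eg, death_grp),  # event-group index per death
        "event_grp_start": start[eg],  # first sorted row of each event group
        "death_segment_start": eg_start,  # first death row of each event group
        "tie_rank": tie_rank,
        "d_of_row": d_of_row,
    }


def cox_univariate_batch(
    times,
    events,
    X: np.ndarray,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
    beta_cap: float = 15.0,
) -> BatchCoxResult:
    """Univariate Cox PH fits for every column of ``X`` simultaneously.

    Newton-Raphson on the partial likelihood, vectorised across
    features; iteration stops when every gradient is below ``tol`` (or
    after ``max_iter`` rounds).  ``ties`` selects the Efron (default) or
    Breslow approximation; the two coincide exactly on untied data.
    Monotone-likelihood features (|beta| drifting past ``beta_cap``) are
    capped and flagged non-converged; constant features are flagged with
    coefficient 0 and P 1.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if events.sum() < 1:
        raise ValueError("at least one event required")

    lay = _risk_set_layout(times, events)
    Xs = X[lay["order"]]
    death_rows = lay["death_rows"]
    gpos = lay["death_grp_pos"]
    eg_start = lay["event_grp_start"]
    seg_start = lay["death_segment_start"]
    if ties == "efron":
        phi = (lay["tie_rank"] / lay["d_of_row"])[:, None]
    else:
        phi = np.zeros((len(death_rows), 1))

    constant = Xs.std(axis=0) == 0
    beta = np.zeros(p)
    active = ~constant
    converged = np.zeros(p, dtype=bool)
    hess = np.full(p, np.nan)
    x_death_sum = Xs[death_rows].sum(axis=0)

    for _ in range(max_iter):
        idx = np.flatnonzero(active & ~converged)
        if idx.size == 0:
            break
        Xa = Xs[:, idx]
        eta = Xa * beta[idx]
        w = np.exp(eta)
        wx = w * Xa
        wx2 = wx * Xa
        # risk-set suffix sums at each event-group start
        S0 = np.cumsum(w[::-1], axis=0)[::-1][eg_start]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1][eg_start]
        S2 = np.cumsum(wx2[::-1], axis=0)[::-1][eg_start]
        # tie-group sums over the deaths themselves (Efron correction)
        D0 = np.add.reduceat(w[death_rows], seg_start, axis=0)
        D1 = np.add.reduceat(wx[death_rows], seg_start, axis=0)
        D2 = np.add.reduceat(wx2[death_rows], seg_start, axis=0)
        denom = S0[gpos] - phi * D0[gpos]
        num1 = S1[gpos] - phi * D1[gpos]
        num2 = S2[gpos] - phi * D2[gpos]
        r1 = num1 / denom
        grad = x_death_sum[idx] - r1.sum(axis=0)
        h = (num2 / denom - r1 * r1).sum(axis=0)
        h = np.maximum(h, 1e-12)
        step = np.clip(grad / h, -2.0, 2.0)
        beta[idx] += step
        hess[idx] = h
        newly = np.abs(grad) < tol
        converged[idx] |= newly
        # monotone likelihood guard
        runaway = np.abs(beta[idx]) > beta_cap
        beta[idx] = np.clip(beta[idx], -beta_cap, beta_cap)
        converged[idx] |= runaway  # stop iterating; flagged below

    diverged = np.abs(beta) >= beta_cap
    converged = converged & ~diverged

    coef = np.where(constant, 0.0, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(constant | np.isnan(hess), np.inf, 1.0 / np.sqrt(hess))
        z = np.where(np.isfinite(se) & (se > 0), coef / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals[constant] = 1.0
    converged = converged & ~constant
    return BatchCoxResult(
        coef=coef,
        se=se,
        z=z,
        p=pvals,
        converged=converged,
        constant=constant,
    )
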