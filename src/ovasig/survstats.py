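"""Survival and categorical statistics engine.

Implements Cox proportional-hazards regression (Newton-Raphson on the partial
likelihood with Efron or Breslow tie handling), a vectorized univariate Cox
screen used by the supervised-PC machinery, the Kaplan-Meier product-limit
estimator, the k-group log-rank test, Fisher's exact test and
Benjamini-Hochberg FDR adjustment.

The univariate screen runs Newton-Raphson simultaneously for thousands of
genes via suffix cumulative sums over the risk sets; this is what makes full
re-screening inside every cross-validation fold and permutation affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalFit",
    "KMCurve",
    "TestResult",
    "FisherResult",
    "fit_cox",
    "cox_univariate_batch",
    "km_estimate",
    "logrank_test",
    "fisher_exact",
    "bh_fdr",
    "build_clinical_covariates",
]

MONOTONE_BOUND = 20.0  # |coef| beyond this is treated as a diverging likelihood

_NUMBA_KERNEL = None
_NUMBA_FAILED = False


def _get_numba_kernel():
    """Compile (once) the per-gene scalar Newton kernel; None if numba is absent."""
    global _NUMBA_KERNEL, _NUMBA_FAILED
    if _NUMBA_KERNEL is not None or _NUMBA_FAILED:
        return _NUMBA_KERNEL
    try:
        from numba import njit
    except ImportError:
        _NUMBA_FAILED = True
        return None

    @njit(cache=True)
    def kernel(Xg, is_event, gstart, efron, max_iter, tol, bound):
        G, n = Xg.shape
        out_beta = np.zeros(G)
        out_hess = np.full(G, np.nan)
        for g in range(G):
            beta = 0.0
            hess = np.nan
            for _ in range(max_iter):
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                grad = 0.0
                hess = 0.0
                pos = n - 1
                while pos >= 0:
                    gs = gstart[pos]
                    sd0 = 0.0
                    sd1 = 0.0
                    sd2 = 0.0
                    xsum = 0.0
                    d = 0
                    for j in range(gs, pos + 1):
                        x = Xg[g, j]
                        w = np.exp(beta * x)
                        wx = w * x
                        s0 += w
                        s1 += wx
                        s2 += wx * x
                        if is_event[j]:
                            d += 1
                            sd0 += w
                            sd1 += wx
                            sd2 += wx * x
                            xsum += x
                    if d > 0:
                        grad += xsum
                        for l in range(d):
                            f = l / d if (efron and d > 1) else 0.0
                            den = s0 - f * sd0
                            n1 = (s1 - f * sd1) / den
                            grad -= n1
                            hess += (s2 - f * sd2) / den - n1 * n1
                    pos = gs - 1
                if hess <= 0.0:
                    break
                step = grad / hess
                if step > 2.0:
                    step = 2.0
                elif step < -2.0:
                    step = -2.0
                beta += step
                if beta > bound:
                    beta = bound
                    break
                if beta < -bound:
                    beta = -bound
                    break
                if abs(grad) < tol:
                    break
            out_beta[g] = beta
            out_hess[g] = hess
        return out_beta, out_hess

    _NUMBA_KERNEL = kernel
    return kernel


class CoxError(ValueError):
    """Raised when a Cox fit is infeasible (no events, collinearity, divergence)."""


@dataclass
class SurvivalFit:
    """Cox model fit: per-covariate coefficient, SE, HR with Wald 95% CI, p."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.coef - 1.96 * self.se)
        hi = np.exp(self.coef + 1.96 * self.se)
        return lo, hi

    @property
    def p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "hr": self.hr,
             "hr_ci_low": lo, "hr_ci_high": hi, "p": self.p},
            index=self.names,
        )


@dataclass
class KMCurve:
    """Product-limit survival estimate on the observed event-time grid."""

    times: np.ndarray          # distinct event times, ascending
    surv: np.ndarray           # S(t) immediately after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    n: int
    median: float | None       # smallest t with S(t) <= 0.5, None = not reached

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    haldane: bool = False


def _sort_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    return order, time[order], event[order].astype(bool)


def _tie_group_starts(t_sorted: np.ndarray) -> np.ndarray:
    """Index of the first member of each sample's tie group (= risk-set start)."""
    new = np.r_[True, t_sorted[1:] != t_sorted[:-1]]
    gid = np.cumsum(new) - 1
    return np.flatnonzero(new)[gid]


def cox_univariate_batch(X, time, event, ties: str = "efron",
                         max_iter: int = 30, tol: float = 1e-8):
    """Univariate Cox regression for every column of ``X`` simultaneously.

    Parameters
    ----------
    X
        ``(n_samples, n_vars)`` covariate matrix; one independent univariate
        model is fitted per column.
    ties
        ``"efron"`` (default) or ``"breslow"``; identical on tie-free data.

    Returns
    -------
    coef, se, p : arrays of length ``n_vars``
        Zero-variance columns get ``coef = 0``, ``se = inf``, ``p = 1``.
        Diverging columns (monotone likelihood) are clipped at +/-20 with
        ``p`` from the clipped Wald statistic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, G = X.shape
    order, t, e = _sort_survival(time, event)
    if not e.any():
        raise CoxError("no events in survival data")
    Xs = X[order]
    gstart = _tie_group_starts(t)
    ev_idx = np.flatnonzero(e)

    # tie structure among events (needed for Efron)
    ev_gstart = gstart[ev_idx]
    uniq_starts, d_counts = np.unique(ev_gstart, return_counts=True)
    has_ties = bool((d_counts > 1).any()) and ties == "efron"
    tied_groups = []
    if has_ties:
        for s, d in zip(uniq_starts, d_counts):
            if d > 1:
                members = ev_idx[ev_gstart == s]
                tied_groups.append((int(s), members))
        tied_set = {int(s) for s, _ in tied_groups}
        untied_ev = np.array([i for i in ev_idx if int(gstart[i]) not in tied_set], dtype=int)
    else:
        untied_ev = ev_idx

    var0 = X.std(axis=0) == 0

    kernel = _get_numba_kernel()
    if kernel is not None:
        beta = np.zeros(G)
        hess = np.full(G, np.nan)
        cols = np.flatnonzero(~var0)
        if cols.size:
            Xg = np.ascontiguousarray(Xs[:, cols].T)
            b, h = kernel(Xg, e.astype(np.int8), gstart.astype(np.int64),
                          ties == "efron", max_iter, tol, MONOTONE_BOUND)
            beta[cols] = b
            hess[cols] = h
        se = np.full(G, np.inf)
        pos = (hess > 0) & ~var0
        se[pos] = 1.0 / np.sqrt(hess[pos])
        z = np.zeros(G)
        finite = np.isfinite(se) & (se > 0)
        z[finite] = beta[finite] / se[finite]
        p = 2.0 * stats.norm.sf(np.abs(z))
        beta[var0] = 0.0
        p[var0] = 1.0
        return beta, se, p

    trivial_gather = bool(np.all(gstart == np.arange(n)))  # no ties anywhere

    def newton(cols: np.ndarray, Xc: np.ndarray):
        """Newton-Raphson on a column block; returns (beta, hess) for the block."""
        g = Xc.shape[1]
        beta = np.zeros(g)
        hess = np.full(g, np.nan)
        active = np.ones(g, dtype=bool)
        Xev = Xc[untied_ev]
        xev_sum = Xev.sum(axis=0)
        for _ in range(max_iter):
            idx = np.flatnonzero(active)
            Xa = Xc if idx.size == g else Xc[:, idx]
            ba = beta if idx.size == g else beta[idx]
            w = np.exp(np.clip(Xa * ba, -500, 500))
            wx = w * Xa
            wx2 = wx * Xa
            rc0 = np.cumsum(w[::-1], axis=0)[::-1]
            rc1 = np.cumsum(wx[::-1], axis=0)[::-1]
            rc2 = np.cumsum(wx2[::-1], axis=0)[::-1]
            if trivial_gather:
                S0, S1, S2 = rc0, rc1, rc2
            else:
                S0, S1, S2 = rc0[gstart], rc1[gstart], rc2[gstart]
            r1 = S1[untied_ev] / S0[untied_ev]
            grad = (xev_sum if idx.size == g else Xev[:, idx].sum(axis=0)) - r1.sum(axis=0)
            h = (S2[untied_ev] / S0[untied_ev] - r1 ** 2).sum(axis=0)
            if has_ties:
                for s, members in tied_groups:
                    d = len(members)
                    sd0 = w[members].sum(axis=0)
                    sd1 = wx[members].sum(axis=0)
                    sd2 = wx2[members].sum(axis=0)
                    grad += (Xa[members]).sum(axis=0)
                    for l in range(d):
                        f = l / d
                        den = S0[s] - f * sd0
                        n1 = (S1[s] - f * sd1) / den
                        grad -= n1
                        h += (S2[s] - f * sd2) / den - n1 ** 2
            step = np.where(h > 0, grad / np.where(h > 0, h, 1.0), 0.0)
            step = np.clip(step, -2.0, 2.0)
            ba = np.clip(ba + step, -MONOTONE_BOUND, MONOTONE_BOUND)
            beta[idx] = ba
            hess[idx] = h
            still = (np.abs(grad) > tol) & (np.abs(ba) < MONOTONE_BOUND) & (h > 0)
            if not still.any():
                break
            active[idx] = still
        return beta, hess

    cols = np.flatnonzero(~var0)
    beta = np.zeros(G)
    hess = np.full(G, np.nan)
    if cols.size:
        Xc = Xs if cols.size == G else Xs[:, cols]
        b, h = newton(cols, Xc)
        beta[cols] = b
        hess[cols] = h

    se = np.full(G, np.inf)
    pos = (hess > 0) & ~var0
    se[pos] = 1.0 / np.sqrt(hess[pos])
    z = np.zeros(G)
    finite = np.isfinite(se) & (se > 0)
    z[finite] = beta[finite] / se[finite]
    p = 2.0 * stats.norm.sf(np.abs(z))
    beta[var0] = 0.0
    p[var0] = 1.0
    return beta, se, p


def fit_cox(covariates, time, event, ties: str = "efron",
            names: list[str] | None = None, max_iter: int = 100,
            tol: float = 1e-8) -> SurvivalFit:
    """Multivariate Cox proportional-hazards fit via Newton-Raphson.

    ``covariates`` may be a DataFrame (column names kept) or 2-D array.
    Converged when the gradient norm falls below ``tol``.  Raises
    :class:`CoxError` for no events, zero-variance covariates or a diverging
    (monotone-likelihood) coefficient.
    """
    if isinstance(covariates, pd.DataFrame):
        names = names or list(covariates.columns)
        Xmat = covariates.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(covariates, dtype=float)
        if Xmat.ndim == 1:
            Xmat = Xmat[:, None]
        names = names or [f"x{i}" for i in range(Xmat.shape[1])]
    if not np.all(np.isfinite(Xmat)):
        raise CoxError("covariates contain non-finite values")
    n, p = Xmat.shape
    sds = Xmat.std(axis=0)
    if (sds == 0).any():
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise CoxError(f"zero-variance covariate(s): {bad}")

    order, t, e = _sort_survival(time, event)
    if not e.any():
        raise CoxError("no events in survival data")
    Xs = Xmat[order]
    gstart = _tie_group_starts(t)
    ev_idx = np.flatnonzero(e)
    ev_gstart = gstart[ev_idx]
    groups = []  # (risk start, member event indices)
    for s in np.unique(ev_gstart):
        groups.append((int(s), ev_idx[ev_gstart == s]))

    beta = np.zeros(p)
    ll = -np.inf
    for _ in range(max_iter):
        eta = Xs @ beta
        w = np.exp(np.clip(eta, -500, 500))
        wx = w[:, None] * Xs
        wxx = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
        C0 = np.cumsum(w[::-1])[::-1]
        C1 = np.cumsum(wx[::-1], axis=0)[::-1]
        C2 = np.cumsum(wxx[::-1], axis=0)[::-1]

        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for s, members in groups:
            d = len(members)
            S0, S1, S2 = C0[s], C1[s], C2[s]
            sd0 = w[members].sum()
            sd1 = wx[members].sum(axis=0)
            sd2 = wxx[members].sum(axis=0)
            ll += eta[members].sum()
            grad += Xs[members].sum(axis=0)
            for l in range(d):
                f = l / d if (ties == "efron" and d > 1) else 0.0
                den = S0 - f * sd0
                n1 = (S1 - f * sd1) / den
                n2 = (S2 - f * sd2) / den
                ll -= np.log(den)
                grad -= n1
                info += n2 - np.outer(n1, n1)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError("singular information matrix (collinear covariates?)") from exc
        nrm = np.linalg.norm(step)
        if nrm > 5.0:
            step *= 5.0 / nrm
        beta = beta + step
        if np.abs(beta).max() > MONOTONE_BOUND:
            raise CoxError(
                "monotone likelihood detected (coefficient diverging beyond "
                f"{MONOTONE_BOUND}); the data perfectly separate the risk sets"
            )
        if np.linalg.norm(grad) < tol:
            break
    else:
        warnings.warn("Cox Newton-Raphson did not reach gradient tolerance", RuntimeWarning)

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return SurvivalFit(names=names, coef=beta, se=se, loglik=float(ll))


def km_estimate(time, event, groups=None) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit curves, one per group label.

    With ``groups=None`` a single curve keyed ``"all"`` is returned.  The
    median is the smallest observed event time with ``S(t) <= 0.5``; ``None``
    when the curve never crosses 0.5 ("not reached").
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if groups is None:
        groups = np.array(["all"] * len(time))
    groups = np.asarray(groups)
    out: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        t, e = time[m], event[m]
        ev_times = np.unique(t[e == 1])
        surv = []
        at_risk = []
        s = 1.0
        for et in ev_times:
            n_risk = int((t >= et).sum())
            d = int(((t == et) & (e == 1)).sum())
            s *= 1.0 - d / n_risk
            surv.append(s)
            at_risk.append(n_risk)
        surv_arr = np.asarray(surv)
        median = None
        crossing = np.flatnonzero(surv_arr <= 0.5)
        if crossing.size:
            median = float(ev_times[crossing[0]])
        out[str(g)] = KMCurve(
            times=ev_times, surv=surv_arr, at_risk=np.asarray(at_risk, dtype=int),
            n=int(m.sum()), median=median,
        )
    return out


def logrank_test(groups, time, event) -> TestResult:
    """k-group log-rank test (O-E chi-square, hypergeometric variance)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    for g in labels:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    if event.sum() == 0:
        raise ValueError("no events")

    ind = np.stack([(groups == g).astype(float) for g in labels[:-1]], axis=1)  # n x (k-1)
    ev_times = np.unique(time[event == 1])
    U = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for et in ev_times:
        risk = time >= et
        n_j = risk.sum()
        d_j = int(((time == et) & (event == 1)).sum())
        n_g = ind[risk].sum(axis=0)                       # at risk per group (first k-1)
        o_g = ind[(time == et) & (event == 1)].sum(axis=0)
        e_g = d_j * n_g / n_j
        U += o_g - e_g
        if n_j > 1:
            frac = n_g / n_j
            cov = (np.diag(frac) - np.outer(frac, frac)) * d_j * (n_j - d_j) / (n_j - 1)
            V += cov
    if np.allclose(V, 0):
        return TestResult(statistic=0.0, p_value=1.0, df=k - 1)
    chi2 = float(U @ np.linalg.solve(V, U))
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return TestResult(statistic=chi2, p_value=p, df=k - 1)


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table of nonnegative integers.

    The two-sided p sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one.  The odds ratio
    is ``ad/bc``; if any cell is zero it is computed with the Haldane +0.5
    correction and flagged.  A zero margin is an error.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("fisher_exact needs a 2x2 table of nonnegative integers")
    tab = tab.astype(int)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("fisher_exact: zero margin, p undefined")
    a, b = tab[0]
    c, d = tab[1]
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        return FisherResult(odds_ratio=float(orr), p_value=float(p), haldane=True)
    return FisherResult(odds_ratio=a * d / (b * c), p_value=float(p), haldane=False)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_clinical_covariates(clinical, include=("age", "stage", "grade", "debulking")):
    """Binary clinical covariates for multivariate adjustment.

    Coding: age >= 65 vs < 65; advanced stage (3/4) vs early (1/2); grade 3 vs
    1-2; suboptimal (or grossly visible) vs optimal (no visible) debulking.
    Returns a DataFrame (NaN where the covariate is missing); complete-case
    filtering is the caller's responsibility.
    """
    df = clinical.data
    out = pd.DataFrame(index=df.index)
    if "age" in include:
        out["age_ge65"] = (df["age_years"] >= 65).astype(float).where(df["age_years"].notna())
    if "stage" in include:
        out["advanced_stage"] = (df["stage"] >= 3).astype(float).where(df["stage"].notna())
    if "grade" in include:
        out["high_grade"] = (df["grade"] >= 3).astype(float).where(df["grade"].notna())
    if "debulking" in include:
        deb = df["debulking"].replace({"unknown": np.nan})
        out["suboptimal_debulking"] = deb.map(
            {"optimal": 0.0, "no_visible": 0.0, "suboptimal": 1.0, "grossly_visible": 1.0}
        )
    return out
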