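"""Pathway-activation signatures via metagene + Bayesian probit regression.

A signature is trained on arrays with experimentally controlled pathway
activation: the top discriminating genes (by |Welch t|) form a signature
submatrix whose leading singular vector defines a one-dimensional metagene;
a Bayesian probit regression of on/off status on the metagene score is fitted
by the Albert-Chib latent-variable Gibbs sampler (zero-mean normal prior).
Tumors are scored by their posterior predictive activation probability;
probability > 0.5 calls the pathway active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from . import survstats
from .pathways import welch_t_scores

__all__ = [
    "PathwaySignature",
    "ActivationCall",
    "train_signature",
    "predict_activation",
    "risk_pathway_association",
]


@dataclass
class PathwaySignature:
    """Trained activation signature.

    ``loadings`` is the unit-norm leading singular vector over the signature
    genes; ``coef_draws`` holds retained Gibbs draws of the probit intercept
    and slope, used for posterior-predictive probabilities.
    """

    genes: list[str]
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    loadings: np.ndarray
    coef_draws: np.ndarray          # (n_mc, 2): intercept, slope
    seed: int
    score_scale: float              # SD of training metagene scores

    @property
    def coef_mean(self) -> np.ndarray:
        return self.coef_draws.mean(axis=0)

    @property
    def coef_sd(self) -> np.ndarray:
        return self.coef_draws.std(axis=0, ddof=1)


@dataclass
class ActivationCall:
    """Per-sample activation probability and binary call (prob > 0.5)."""

    probability: pd.Series

    @property
    def call(self) -> pd.Series:
        return (self.probability > 0.5).rename("active")


def _gibbs_probit(x: np.ndarray, y: np.ndarray, n_mc: int, burn_in: int,
                  prior_var: float, rng: np.random.Generator) -> np.ndarray:
    """Albert-Chib Gibbs sampler for probit regression with N(0, v I) prior."""
    n = len(y)
    xmat = np.column_stack([np.ones(n), x])
    prec = xmat.T @ xmat + np.eye(2) / prior_var
    cov = np.linalg.inv(prec)
    chol = np.linalg.cholesky(cov)
    beta = np.zeros(2)
    draws = np.empty((n_mc, 2))
    lo = np.where(y == 1, 0.0, -np.inf)
    hi = np.where(y == 1, np.inf, 0.0)
    for t in range(burn_in + n_mc):
        eta = xmat @ beta
        # truncated-normal latent variables via the inverse-CDF method
        a = stats.norm.cdf(lo - eta)
        b = stats.norm.cdf(hi - eta)
        u = rng.uniform(a, np.maximum(b, a + 1e-12))
        z = eta + stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
        mean = cov @ (xmat.T @ z)
        beta = mean + chol @ rng.standard_normal(2)
        if t >= burn_in:
            draws[t - burn_in] = beta
    return draws


def train_signature(x_on: ExpressionMatrix, x_off: ExpressionMatrix,
                    n_genes: int = 100, n_mc: int = 5000, burn_in: int = 1000,
                    prior_var: float = 100.0, seed: int = 0) -> PathwaySignature:
    """Train an activation signature from on/off experimental arrays.

    Selects the ``n_genes`` genes with largest |Welch t| between classes,
    standardizes them on the pooled training arrays, takes the leading
    singular vector as metagene loadings (oriented so "on" arrays score
    higher) and fits the Bayesian probit of class on metagene score.
    """
    if x_on.n_samples < 5 or x_off.n_samples < 5:
        raise ValueError("need at least 5 arrays per class")
    if x_on.gene_ids != x_off.gene_ids:
        raise ValueError("on/off arrays must share the same gene ids in order")
    values = np.concatenate([x_on.values, x_off.values], axis=1)
    y = np.array([1] * x_on.n_samples + [0] * x_off.n_samples)

    t = welch_t_scores(values, y == 1)
    order = np.argsort(-np.abs(t), kind="stable")[:n_genes]
    genes = [x_on.gene_ids[i] for i in order]
    sub = values[order, :]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - mean[:, None]) / sd[:, None]
    u_mat, _, _ = np.linalg.svd(z, full_matrices=False)
    loadings = u_mat[:, 0]
    score = z.T @ loadings
    if score[y == 1].mean() < score[y == 0].mean():
        loadings = -loadings
        score = -score
    scale = max(score.std(ddof=1), 1e-12)
    score = score / scale

    if score[y == 1].min() > score[y == 0].max():
        warnings.warn("training classes perfectly separated; prior regularizes the fit")
    rng = np.random.default_rng(seed)
    draws = _gibbs_probit(score, y, n_mc=n_mc, burn_in=burn_in,
                          prior_var=prior_var, rng=rng)
    return PathwaySignature(
        genes=genes, gene_mean=mean, gene_sd=sd, loadings=loadings,
        coef_draws=draws, seed=seed, score_scale=float(scale),
    )


def predict_activation(sig: PathwaySignature, tumors: ExpressionMatrix) -> ActivationCall:
    """Posterior-mean probit activation probability for each tumor.

    Tumors must be batch co-adjusted with the signature's training arrays;
    standardization, loadings and coefficient draws are frozen from training.
    """
    idx = {g: i for i, g in enumerate(tumors.gene_ids)}
    missing = [g for g in sig.genes if g not in idx]
    if missing:
        raise KeyError(f"signature gene(s) absent from tumor matrix: {missing}")
    rows = [idx[g] for g in sig.genes]
    z = (tumors.values[rows, :] - sig.gene_mean[:, None]) / sig.gene_sd[:, None]
    score = (z.T @ sig.loadings) / sig.score_scale
    eta = sig.coef_draws[:, 0][None, :] + np.outer(score, sig.coef_draws[:, 1])
    prob = stats.norm.cdf(eta).mean(axis=1)
    return ActivationCall(probability=pd.Series(prob, index=tumors.sample_ids,
                                                name="activation_probability"))


def risk_pathway_association(calls: ActivationCall, risk_groups: pd.Series):
    """Odds ratio of pathway activation in high- vs low-risk tumors.

    Cross-tabulates the binary activation call against the risk group over
    the overlapping samples and returns ``(odds_ratio, (ci_low, ci_high),
    FisherResult)`` with a Woolf (log-OR normal) 95% CI; a zero cell falls
    back to the Haldane correction with a warning.
    """
    common = [s for s in calls.probability.index if s in set(risk_groups.index)]
    if len(common) < 10:
        raise ValueError("need at least 10 overlapping samples")
    act = calls.call.loc[common].to_numpy()
    high = (risk_groups.loc[common].astype(str) == "high").to_numpy()
    a = int((act & high).sum())        # active, high risk
    b = int((act & ~high).sum())       # active, low risk
    c = int((~act & high).sum())
    d = int((~act & ~high).sum())
    margins_ok = min(a + b, c + d, a + c, b + d) > 0
    fisher = survstats.fisher_exact([[a, b], [c, d]]) if margins_ok else None
    if fisher is None:
        warnings.warn("zero margin in activation x risk table; p undefined")
    if min(a, b, c, d) == 0:
        warnings.warn("zero cell in activation x risk table; Haldane-corrected OR")
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    orr = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    ci = (float(np.exp(np.log(orr) - 1.96 * se)), float(np.exp(np.log(orr) + 1.96 * se)))
    return float(orr), ci, fisher
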