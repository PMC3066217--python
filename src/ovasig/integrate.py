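"""Building a composite training set from multiple expression cohorts.

Covers matrix-level quantile normalization (a proxy for probe-level
summarization, which needs raw arrays), RLE-based outlier QC, cross-platform
id mapping and merging on the common gene space, the RV coefficient of
co-structure, classical MDS for visual batch assessment, empirical-Bayes
location/scale batch adjustment (parametric and nonparametric), and the
two-cluster survival sanity check run per cohort before merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ClinicalTable, ExpressionMatrix, IdMap, ValidationError
from . import survstats

__all__ = [
    "BatchAdjustModel",
    "QCReport",
    "quantile_normalize",
    "rle_outlier_flags",
    "map_and_merge",
    "rv_coefficient",
    "classical_mds",
    "combat_adjust",
    "two_cluster_survival_qc",
]


@dataclass
class BatchAdjustModel:
    """Fitted empirical-Bayes location/scale batch model.

    ``gamma_star``/``delta_star`` are the shrunken per-gene additive and scale
    batch effects (genes x batches); ``alpha`` the per-gene grand location;
    ``beta_cov`` the covariate effects; the per-batch hyperparameters are the
    normal prior mean/variance of the additive effects and the inverse-gamma
    shape/scale of the squared scale effects.
    """

    batches: list[str]
    gamma_star: np.ndarray
    delta_star: np.ndarray
    alpha: np.ndarray
    beta_cov: np.ndarray | None
    sigma: np.ndarray
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    mode: str = "parametric"


@dataclass
class QCReport:
    rle_median: pd.Series | None = None
    rle_iqr: pd.Series | None = None
    outlier_flags: list[str] = field(default_factory=list)
    rv: dict[tuple[str, str], float] = field(default_factory=dict)
    mds: pd.DataFrame | None = None


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean distribution of order statistics.

    After normalization every column shares the identical sorted value
    vector; within-sample rank order is preserved.
    """
    if em.n_samples == 1:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return em.copy()
    v = em.values
    order = np.argsort(v, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(v, order, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(v)
    np.put_along_axis(out, order, target[:, None], axis=0)
    return ExpressionMatrix(list(em.gene_ids), list(em.sample_ids), out, em.batch)


def rle_outlier_flags(em: ExpressionMatrix, median_thresh: float = 0.5,
                      iqr_thresh: float = 1.0) -> QCReport:
    """Relative-log-expression outlier screen.

    RLE_gj = x_gj - median_g over samples; a sample is flagged when the
    absolute median of its RLE distribution exceeds ``median_thresh`` or its
    IQR exceeds ``iqr_thresh`` (both in log2 units).
    """
    if em.n_samples < 3:
        raise ValueError("RLE QC needs at least 3 samples")
    rle = em.values - np.median(em.values, axis=1, keepdims=True)
    med = np.median(rle, axis=0)
    q75, q25 = np.percentile(rle, [75, 25], axis=0)
    iqr = q75 - q25
    flags = [s for s, m, i in zip(em.sample_ids, med, iqr)
             if abs(m) > median_thresh or i > iqr_thresh]
    return QCReport(
        rle_median=pd.Series(med, index=em.sample_ids),
        rle_iqr=pd.Series(iqr, index=em.sample_ids),
        outlier_flags=flags,
    )


def _collapse(df: pd.DataFrame, how: str) -> pd.DataFrame:
    if how == "mean":
        return df.groupby(level=0, sort=False).mean()
    if how == "max_var":
        rows = []
        genes = []
        for gene, grp in df.groupby(level=0, sort=False):
            rows.append(grp.to_numpy()[int(np.argmax(grp.var(axis=1).to_numpy()))])
            genes.append(gene)
        return pd.DataFrame(rows, index=genes, columns=df.columns)
    raise ValueError(f"unknown collapse rule {how!r}")


def map_and_merge(cohorts: dict[str, ExpressionMatrix], idmap: IdMap | None = None,
                  collapse: str = "mean") -> ExpressionMatrix:
    """Map cohorts onto a shared gene namespace and join on the intersection.

    Source ids found in ``idmap`` are translated; ids outside the map pass
    through unchanged.  Many-to-one rows are collapsed by ``collapse``
    (``"mean"`` averages mapped rows, ``"max_var"`` keeps the most variable
    source row).  The batch label of the merged matrix is the cohort name.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    mapped: dict[str, pd.DataFrame] = {}
    for name, em in cohorts.items():
        genes = [idmap[g] if (idmap is not None and g in idmap) else g
                 for g in em.gene_ids]
        df = pd.DataFrame(em.values, index=genes, columns=em.sample_ids)
        if df.index.has_duplicates:
            df = _collapse(df, collapse)
        mapped[name] = df

    names = list(mapped)
    common = list(mapped[names[0]].index)
    for name in names[1:]:
        here = set(mapped[name].index)
        common = [g for g in common if g in here]
        if not common:
            raise ValidationError(
                f"empty gene intersection between cohorts {names[0]!r} and {name!r}"
            )
    blocks = [mapped[name].loc[common] for name in names]
    values = np.concatenate([b.to_numpy() for b in blocks], axis=1)
    sample_ids = [s for b in blocks for s in b.columns]
    batch = [name for name, b in zip(names, blocks) for _ in b.columns]
    return ExpressionMatrix(common, sample_ids, values, batch=batch)


def rv_coefficient(x: ExpressionMatrix | np.ndarray, y: ExpressionMatrix | np.ndarray,
                   modified: bool = False) -> float:
    """RV coefficient of co-structure between two sample-matched matrices.

    Each matrix (genes x samples) is row-centered; with S = X'X the
    sample-space cross-product, RV = trace(Sx Sy) / sqrt(trace(Sx^2)
    trace(Sy^2)) in [0, 1].  Invariant to orthonormal rotation of gene space.

    The classical RV carries an upward bias for unrelated high-dimensional
    data because the diagonal of S (per-sample norms) dominates the traces
    (the expected value for independent noise is roughly 1/(1 + n/G)).
    ``modified=True`` zeroes the diagonals before taking traces, which drives
    the statistic to ~0 for unrelated matrices while keeping RV(X, X) = 1.
    """
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, ExpressionMatrix) else np.asarray(y, dtype=float)
    if xv.shape[1] != yv.shape[1]:
        raise ValueError("matrices must share the same samples (columns)")
    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = yv - yv.mean(axis=1, keepdims=True)
    sx = xc.T @ xc
    sy = yc.T @ yc
    if modified:
        np.fill_diagonal(sx, 0.0)
        np.fill_diagonal(sy, 0.0)
    denom = np.sqrt(np.sum(sx * sx) * np.sum(sy * sy))
    if denom == 0:
        raise ValueError("zero-variance matrix: RV undefined")
    return float(np.sum(sx * sy) / denom)


def classical_mds(em: ExpressionMatrix, distance: str = "euclidean",
                  n_components: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of the samples.

    Double-centers the squared sample-distance matrix and embeds on the top
    eigenvectors; an exact Euclidean configuration is recovered when one
    exists.  ``distance`` is ``"euclidean"`` on expression columns or
    ``"correlation"`` (1 - Pearson r).
    """
    if em.n_samples < 3:
        raise ValueError("MDS needs at least 3 samples")
    v = em.values
    if distance == "euclidean":
        sq = (v * v).sum(axis=0)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (v.T @ v)
        d2 = np.maximum(d2, 0.0)
    elif distance == "correlation":
        c = np.corrcoef(v.T)
        d2 = (1.0 - c) ** 2
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if not np.all(np.isfinite(d2)):
        raise ValueError("non-finite distances")
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)[None, :]
    return pd.DataFrame(coords, index=em.sample_ids,
                        columns=[f"MDS{i + 1}" for i in range(n_components)])


def _design_matrix(batch_idx: np.ndarray, n_batches: int, covariates) -> np.ndarray:
    n = len(batch_idx)
    x_batch = np.zeros((n, n_batches))
    x_batch[np.arange(n), batch_idx] = 1.0
    if covariates is None:
        return x_batch
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    x = np.concatenate([x_batch, cov], axis=1)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariates are confounded with batch (design not full rank)")
    return x


def combat_adjust(em: ExpressionMatrix, batch=None, covariates=None,
                  mode: str = "parametric", n_mc: int = 2000, seed: int = 0,
                  eb_tol: float = 1e-6, eb_max_iter: int = 200):
    """Empirical-Bayes location/scale batch adjustment.

    Standardizes each gene using pooled location/scale (protecting any
    biological ``covariates``), estimates per-gene additive (gamma) and
    multiplicative (delta) batch effects, shrinks them toward batch-level
    priors — normal / inverse-gamma with method-of-moments hyperparameters and
    an iterative joint solution in ``parametric`` mode, likelihood-weighted
    posterior means over a Monte-Carlo subsample of genes in
    ``nonparametric`` mode — and returns the adjusted matrix together with
    the fitted :class:`BatchAdjustModel`.
    """
    if batch is None:
        batch = em.batch
    if batch is None:
        raise ValueError("batch labels required (matrix carries none)")
    batch = np.asarray([str(b) for b in batch])
    if len(batch) != em.n_samples:
        raise ValueError("batch labels length != number of samples")
    batch_names = list(pd.unique(batch))
    n_batches = len(batch_names)
    if n_batches == 1:
        warnings.warn("single batch: no adjustment applied")
        G = em.n_genes
        model = BatchAdjustModel(
            batches=batch_names,
            gamma_star=np.zeros((G, 1)), delta_star=np.ones((G, 1)),
            alpha=em.values.mean(axis=1), beta_cov=None,
            sigma=em.values.std(axis=1), gamma_bar=np.zeros(1), tau2=np.ones(1),
            a_prior=np.ones(1), b_prior=np.ones(1), mode=mode,
        )
        return em.copy(), model
    sizes = pd.Series(batch).value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batch(es) with a single sample: {list(small.index)}")

    y = em.values  # genes x samples
    G, n = y.shape
    bidx = np.array([batch_names.index(b) for b in batch])
    x = _design_matrix(bidx, n_batches, covariates)
    n_i = np.array([(bidx == i).sum() for i in range(n_batches)], dtype=float)

    # per-gene OLS fit of the full design
    bhat, *_ = np.linalg.lstsq(x, y.T, rcond=None)    # (p, G)
    grand = (n_i / n) @ bhat[:n_batches]              # weighted grand location, per gene
    resid = y.T - x @ bhat
    sigma2 = (resid ** 2).mean(axis=0)                # per gene, pooled
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))

    stand_mean = np.tile(grand, (n, 1))
    if covariates is not None:
        stand_mean = stand_mean + x[:, n_batches:] @ bhat[n_batches:]
    z = (y - stand_mean.T) / sigma[:, None]           # genes x samples

    gamma_hat = np.stack([z[:, bidx == i].mean(axis=1) for i in range(n_batches)], axis=1)
    delta_hat = np.stack([z[:, bidx == i].var(axis=1, ddof=1) for i in range(n_batches)], axis=1)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    m = delta_hat.mean(axis=0)
    s2 = delta_hat.var(axis=0, ddof=1)
    a_prior = (2.0 * s2 + m ** 2) / s2
    b_prior = (m * s2 + m ** 3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    if mode == "parametric":
        for i in range(n_batches):
            g_new = ((n_i[i] * tau2[i] * gamma_hat[:, i] + delta_hat[:, i] * gamma_bar[i])
                     / (n_i[i] * tau2[i] + delta_hat[:, i]))
            d_new = delta_hat[:, i].copy()
            zi = z[:, bidx == i]
            for _ in range(eb_max_iter):
                g_old, d_old = g_new, d_new
                g_new = ((n_i[i] * tau2[i] * gamma_hat[:, i] + d_old * gamma_bar[i])
                         / (n_i[i] * tau2[i] + d_old))
                ssq = ((zi - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (b_prior[i] + 0.5 * ssq) / (n_i[i] / 2.0 + a_prior[i] - 1.0)
                if (np.abs(g_new - g_old).max() < eb_tol
                        and np.abs(d_new - d_old).max() < eb_tol):
                    break
            gamma_star[:, i] = g_new
            delta_star[:, i] = np.sqrt(np.maximum(d_new, 1e-12))
    elif mode == "nonparametric":
        rng = np.random.default_rng(seed)
        for i in range(n_batches):
            zi = z[:, bidx == i]
            ssq = (zi ** 2).sum(axis=1)
            s1 = zi.sum(axis=1)
            k = min(n_mc, G - 1)
            for g in range(G):
                pool = rng.choice(G - 1, size=k, replace=False)
                pool = pool + (pool >= g)                 # exclude gene g itself
                gp = gamma_hat[pool, i]
                dp = np.maximum(delta_hat[pool, i], 1e-12)
                loglh = (-0.5 * n_i[i] * np.log(2.0 * np.pi * dp)
                         - (ssq[g] - 2.0 * gp * s1[g] + n_i[i] * gp ** 2) / (2.0 * dp))
                w = np.exp(loglh - loglh.max())
                w_sum = w.sum()
                gamma_star[g, i] = float((w * gp).sum() / w_sum)
                delta_star[g, i] = float(np.sqrt((w * dp).sum() / w_sum))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    adj = (z - gamma_star[:, bidx]) / delta_star[:, bidx]
    adj = adj * sigma[:, None] + stand_mean.T
    out = ExpressionMatrix(list(em.gene_ids), list(em.sample_ids), adj, list(batch))
    model = BatchAdjustModel(
        batches=batch_names, gamma_star=gamma_star, delta_star=delta_star,
        alpha=grand, beta_cov=None if covariates is None else bhat[n_batches:].T,
        sigma=sigma, gamma_bar=gamma_bar, tau2=tau2,
        a_prior=a_prior, b_prior=b_prior, mode=mode,
    )
    return out, model


def two_cluster_survival_qc(em: ExpressionMatrix, clinical: ClinicalTable):
    """Cluster a cohort into its 2 predominant expression groups and test OS.

    Average-linkage hierarchical clustering on 1 - Pearson correlation
    between samples, cut at two clusters, followed by a log-rank test of
    overall survival between them.  A significant split warns that technical
    structure within the cohort may be confounded with outcome.

    Returns ``(labels, TestResult-or-None)``; the test is skipped (None, with
    a warning) when a cluster has fewer than 2 samples.
    """
    if em.n_samples < 10:
        raise ValueError("survival QC needs at least 10 samples")
    clin = clinical.aligned_to(em.sample_ids)
    corr = np.corrcoef(em.values.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    zlink = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(zlink, t=2, criterion="maxclust")
    sizes = np.bincount(labels)[1:]
    if sizes.min() < 2:
        warnings.warn("degenerate two-cluster cut (a cluster has < 2 samples); p not computed")
        return labels, None
    res = survstats.logrank_test(labels, clin.os_months, clin.event)
    return labels, res
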