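"""Gene-set characterization of risk phenotypes.

Two complementary views: two-class gene-set analysis with the restandardized
maxmean statistic and permutation p-values, and over-representation analysis
of a differentially-expressed gene list with the conservative jackknifed
Fisher (EASE) score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSetCollection
from .survstats import bh_fdr

__all__ = [
    "welch_t_scores",
    "select_deg",
    "gsa",
    "ease_analysis",
]


def welch_t_scores(values: np.ndarray, class1: np.ndarray) -> np.ndarray:
    """Welch (unequal-variance) t statistic per gene, class 1 minus class 0."""
    x1 = values[:, class1]
    x0 = values[:, ~class1]
    n1, n0 = x1.shape[1], x0.shape[1]
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / n1 + v0 / n0)
    denom = np.where(denom == 0, np.inf, denom)
    return (x1.mean(axis=1) - x0.mean(axis=1)) / denom


def _welch_p(values: np.ndarray, class1: np.ndarray) -> np.ndarray:
    x1 = values[:, class1]
    x0 = values[:, ~class1]
    res = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    return res.pvalue


def _two_class_mask(labels, em: ExpressionMatrix):
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != em.n_samples:
        raise ValueError("labels length != number of samples")
    names = list(pd.unique(labels))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 classes, got {names}")
    mask = labels == names[0]
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("both classes need at least 3 samples")
    return mask, names


def select_deg(em: ExpressionMatrix, labels, p_threshold: float = 1e-6):
    """Split genes passing a Welch t-test threshold into up/down lists.

    Direction is relative to the first class label encountered (class 1);
    "up" means higher in class 1.  Returns ``(up, down)`` lists of gene ids.
    """
    mask, _ = _two_class_mask(labels, em)
    t = welch_t_scores(em.values, mask)
    p = _welch_p(em.values, mask)
    passing = p < p_threshold
    genes = np.asarray(em.gene_ids, dtype=object)
    up = list(genes[passing & (t > 0)])
    down = list(genes[passing & (t < 0)])
    return up, down


@dataclass
class GSAResult:
    table: pd.DataFrame   # per set: stat (restandardized), p, direction, size


def _maxmean(scores: np.ndarray, set_idx: list[np.ndarray]) -> np.ndarray:
    """Maxmean statistic per gene set.

    Positive and negative parts of the gene scores are averaged over the full
    set (zeros included); the part with larger magnitude wins and carries its
    sign.
    """
    out = np.empty(len(set_idx))
    pos = np.clip(scores, 0.0, None)
    neg = np.clip(-scores, 0.0, None)
    for k, idx in enumerate(set_idx):
        mp = pos[idx].mean()
        mn = neg[idx].mean()
        out[k] = mp if mp >= mn else -mn
    return out


def gsa(em: ExpressionMatrix, labels, genesets: GeneSetCollection,
        n_perm: int = 200, seed: int = 0, n_restand: int = 200) -> GSAResult:
    """Two-class gene-set analysis with the restandardized maxmean statistic.

    Per-gene Welch t scores feed the maxmean set statistic, which is
    restandardized by the mean/SD of maxmean over ``n_restand`` random gene
    sets of the same size drawn from the whole genome; significance is by
    class-label permutation (two-sided, on the restandardized statistic) with
    the add-one rule.  Sets with no overlap with the gene universe are
    skipped with a warning.
    """
    mask, names = _two_class_mask(labels, em)
    gene_pos = {g: i for i, g in enumerate(em.gene_ids)}
    set_names, set_idx = [], []
    for name, genes in genesets:
        idx = np.array([gene_pos[g] for g in genes if g in gene_pos], dtype=int)
        if idx.size == 0:
            warnings.warn(f"gene set {name!r} has no genes in the matrix; skipped")
            continue
        set_names.append(name)
        set_idx.append(idx)
    if not set_names:
        raise ValueError("no gene set overlaps the expression matrix")

    rng = np.random.default_rng(seed)
    G = em.n_genes
    sizes = sorted({idx.size for idx in set_idx})
    rand_sets = {s: [rng.integers(0, G, size=s) for _ in range(n_restand)] for s in sizes}

    def restandardized(scores: np.ndarray) -> np.ndarray:
        raw = _maxmean(scores, set_idx)
        out = np.empty_like(raw)
        ref_mean, ref_sd = {}, {}
        for s in sizes:
            ref = _maxmean(scores, rand_sets[s])
            ref_mean[s] = ref.mean()
            ref_sd[s] = max(ref.std(ddof=1), 1e-12)
        for k, idx in enumerate(set_idx):
            out[k] = (raw[k] - ref_mean[idx.size]) / ref_sd[idx.size]
        return out

    t_obs = welch_t_scores(em.values, mask)
    stat_obs = restandardized(t_obs)

    n = em.n_samples
    n1 = int(mask.sum())
    exceed = np.zeros(len(set_names), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pmask = np.zeros(n, dtype=bool)
        pmask[perm[:n1]] = True
        t_p = welch_t_scores(em.values, pmask)
        stat_p = restandardized(t_p)
        exceed += np.abs(stat_p) >= np.abs(stat_obs)
    p = (1 + exceed) / (n_perm + 1)
    direction = np.where(stat_obs >= 0, f"up_in_{names[0]}", f"up_in_{names[1]}")
    table = pd.DataFrame(
        {"stat": stat_obs, "p": p, "direction": direction,
         "size": [idx.size for idx in set_idx]},
        index=set_names,
    )
    return GSAResult(table=table)


def ease_analysis(hits, background, categories: GeneSetCollection,
                  fdr_threshold: float = 0.01,
                  systems: dict[str, str] | None = None) -> pd.DataFrame:
    """Over-representation analysis with the jackknifed Fisher (EASE) score.

    For a category with ``k`` hits out of a list of ``n`` genes against a
    background of ``N`` genes of which ``K`` are in the category, the plain
    one-sided Fisher p is ``P(X >= k)`` for hypergeometric X; the EASE score
    removes one hit from the category cell first, ``P(X >= k - 1)``, which is
    conservative and penalizes categories supported by a single gene.  FDR is
    BH, computed within each annotation system when ``systems`` maps category
    names to systems, otherwise across all categories.
    """
    hits = [str(g) for g in hits]
    if not hits:
        raise ValueError("empty hit list")
    bg = {str(g) for g in background}
    stray = [g for g in hits if g not in bg]
    if stray:
        raise ValueError(f"hit(s) outside the background: {stray[:5]}")
    hit_set = set(hits)
    N = len(bg)
    n_list = len(hit_set)

    rows = []
    for name, genes in categories:
        cat = {g for g in genes if g in bg}
        if not cat:
            continue
        K = len(cat)
        k = len(cat & hit_set)
        fisher_p = float(stats.hypergeom.sf(k - 1, N, K, n_list))
        ease_p = float(stats.hypergeom.sf(k - 2, N, K, n_list)) if k >= 1 else 1.0
        rows.append({"category": name, "system": (systems or {}).get(name, "all"),
                     "hits": k, "list_total": n_list, "category_size": K,
                     "background_total": N, "fisher_p": fisher_p, "ease_score": ease_p})
    if not rows:
        raise ValueError("no category overlaps the background")
    df = pd.DataFrame(rows).set_index("category").sort_index()
    df["fdr"] = np.nan
    for _, idx in df.groupby("system").groups.items():
        df.loc[idx, "fdr"] = bh_fdr(df.loc[idx, "ease_score"].to_numpy())
    df["significant"] = df["fdr"] <= fdr_threshold
    return df
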