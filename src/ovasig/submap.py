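"""Subclass mapping: genome-wide correspondence of subclasses across cohorts.

Given two independently labeled cohorts A and B on a shared gene universe,
each A-subclass contributes a marker gene list (top signal-to-noise genes vs
the rest of A) whose enrichment toward the up-regulated end of every
B-subclass's gene ranking is scored with a Kolmogorov-Smirnov running-sum
enrichment score.  Significance comes from permuting the ranking cohort's
sample labels; the two directional p-values are combined with Fisher's
inverse chi-square statistic, whose null is built by resampling from the two
enrichment null distributions, and the combined p-values are BH-FDR adjusted
into the subclass association (SA) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .survstats import bh_fdr

__all__ = [
    "SAMatrix",
    "subclass_markers",
    "snr_scores",
    "enrichment_score",
    "run_submap",
]

MIN_OCCUPANCY = 0.10  # a candidate subclass must hold >= 10% of its cohort


@dataclass
class SAMatrix:
    """SubMap result: directional p's, combined statistics, FDR-adjusted matrix."""

    classes_a: list[str]
    classes_b: list[str]
    es_ab: np.ndarray       # enrichment of marker(Ai) in ranking(Bj)
    es_ba: np.ndarray       # enrichment of marker(Bj) in ranking(Ai), same shape
    p_ab: np.ndarray
    p_ba: np.ndarray
    fisher: np.ndarray      # F_ij = -2 (ln p_ab + ln p_ba)
    p_combined: np.ndarray
    sa: np.ndarray          # BH-FDR adjusted combined p-values

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sa, index=self.classes_a, columns=self.classes_b)


def _validate_labels(labels, n_samples: int) -> np.ndarray:
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != n_samples:
        raise ValueError("labels length != number of samples")
    counts = pd.Series(labels).value_counts()
    low = counts[counts < MIN_OCCUPANCY * n_samples]
    if len(low):
        raise ValueError(
            f"subclass(es) below 10% occupancy: {list(low.index)} "
            f"(counts {list(low.values)} of {n_samples})"
        )
    return labels


def snr_scores(values: np.ndarray, member: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Signal-to-noise ratio per gene: (mu_in - mu_out) / (sd_in + sd_out)."""
    inside = values[:, member]
    outside = values[:, ~member]
    mu_i, mu_o = inside.mean(axis=1), outside.mean(axis=1)
    sd_i, sd_o = inside.std(axis=1, ddof=1), outside.std(axis=1, ddof=1)
    return (mu_i - mu_o) / (sd_i + sd_o + eps)


def subclass_markers(em: ExpressionMatrix, labels, subclass: str, m: int) -> list[str]:
    """Top-m up-regulated marker genes of a subclass versus the rest."""
    labels = _validate_labels(labels, em.n_samples)
    if subclass not in labels:
        raise ValueError(f"unknown subclass {subclass!r}")
    if m > em.n_genes:
        raise ValueError("m cannot exceed the number of genes")
    scores = snr_scores(em.values, labels == subclass)
    order = np.argsort(-scores, kind="stable")[:m]
    return [em.gene_ids[i] for i in order]


def enrichment_score(markers, ranking) -> float:
    """KS running-sum enrichment of a marker set in a ranked gene list.

    Classic unweighted form: walking down the ranking, hits step up by 1/m
    and misses step down by 1/(N-m); the score is the maximum deviation of
    the running sum from zero (signed: the extreme of larger magnitude).
    ES = 1 when all markers lead the list; ES = 0 in the degenerate case
    m = N.
    """
    ranking = list(ranking)
    n = len(ranking)
    marker_set = set(markers)
    if not marker_set:
        raise ValueError("empty marker set")
    missing = marker_set - set(ranking)
    if missing:
        raise ValueError(f"marker(s) outside the ranked universe: {sorted(missing)[:5]}")
    m = len(marker_set)
    if m == n:
        return 0.0
    hit = np.fromiter((g in marker_set for g in ranking), dtype=bool, count=n)
    steps = np.where(hit, 1.0 / m, -1.0 / (n - m))
    running = np.cumsum(steps)
    hi, lo = running.max(), running.min()
    return float(np.clip(hi if hi >= -lo else lo, -1.0, 1.0))


def _es_fast(hit_positions: np.ndarray, n: int, m: int) -> float:
    """Enrichment score from sorted hit positions without building the walk."""
    # running sum just after the k-th hit (position p_k, 0-based):
    #   (k+1)/m - (p_k + 1 - (k+1))/(n - m)
    k = np.arange(1, m + 1)
    up = k / m - (hit_positions + 1 - k) / (n - m)
    down = (k - 1) / m - (hit_positions - (k - 1)) / (n - m)  # just before each hit
    hi = up.max()
    lo = down.min()
    return float(np.clip(hi if hi >= -lo else lo, -1.0, 1.0))


def _es_from_scores(marker_idx: np.ndarray, scores: np.ndarray) -> float:
    """ES of a marker index set against genes ranked by descending score."""
    n = scores.shape[0]
    m = marker_idx.size
    if m == n:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    rank_of = np.empty(n, dtype=np.int64)
    rank_of[order] = np.arange(n)
    pos = np.sort(rank_of[marker_idx])
    return _es_fast(pos, n, m)


def _directional_pvalues(values_a, labels_a, classes_a, values_b, labels_b,
                         classes_b, marker_idx, n_perm, rng):
    """p_AB[i, j] for markers of A-classes against rankings of B, with nulls.

    Returns (es_obs, p, null_es) where null_es has shape (n_classes_b, n_perm)
    stacked per ranking class (the null depends on the ranking cohort only
    through its label permutations).
    """
    n_a, n_b = len(classes_a), len(classes_b)
    es_obs = np.empty((n_a, n_b))
    for j, cb in enumerate(classes_b):
        scores = snr_scores(values_b, labels_b == cb)
        for i in range(n_a):
            es_obs[i, j] = _es_from_scores(marker_idx[i], scores)

    null_es = np.empty((n_a, n_b, n_perm))
    nb = values_b.shape[1]
    for t in range(n_perm):
        perm = rng.permutation(nb)
        plabels = labels_b[perm]
        for j, cb in enumerate(classes_b):
            member = plabels == cb
            scores = snr_scores(values_b, member)
            for i in range(n_a):
                null_es[i, j, t] = _es_from_scores(marker_idx[i], scores)

    p = np.empty((n_a, n_b))
    for i in range(n_a):
        for j in range(n_b):
            p[i, j] = (1 + int((null_es[i, j] >= es_obs[i, j]).sum())) / (n_perm + 1)
    return es_obs, p, null_es


def run_submap(a: ExpressionMatrix, labels_a, b: ExpressionMatrix, labels_b,
               m: int = 100, n_perm: int = 500, seed: int = 0,
               n_fisher_null: int = 5000) -> SAMatrix:
    """Full subclass-mapping run between two labeled cohorts.

    Both cohorts are restricted to their common gene universe.  For each pair
    (Ai, Bj): p_AB from permuting B's labels under the ES of marker(Ai) in
    ranking(Bj); p_BA with the roles swapped; F_ij = -2(ln p_AB + ln p_BA)
    with a null built by drawing p-value pairs from the two ES null
    distributions; BH-FDR across all cells gives the SA matrix.

    Permutation streams are keyed to each cohort's sample ids, so swapping
    the argument order transposes the result exactly.
    """
    common = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if len(common) < 2 * m:
        raise ValueError(
            f"gene universe intersection ({len(common)}) smaller than 2m = {2 * m}"
        )
    av = a.subset_genes(common).values
    bv = b.subset_genes(common).values
    la = _validate_labels(labels_a, a.n_samples)
    lb = _validate_labels(labels_b, b.n_samples)
    classes_a = sorted(pd.unique(la))
    classes_b = sorted(pd.unique(lb))

    # cohort-keyed child seeds: the permutation stream for a cohort does not
    # depend on whether it was passed first or second
    key_a, key_b = tuple(a.sample_ids), tuple(b.sample_ids)
    a_first = key_a <= key_b
    child = np.random.SeedSequence(seed).spawn(2)
    if a_first:
        seq_a, seq_b = child[0], child[1]
    else:
        seq_a, seq_b = child[1], child[0]
    rng_a, rng_b = np.random.default_rng(seq_a), np.random.default_rng(seq_b)

    def markers_for(values, labels, classes):
        out = []
        for c in classes:
            scores = snr_scores(values, labels == c)
            out.append(np.argsort(-scores, kind="stable")[:m])
        return out

    mk_a = markers_for(av, la, classes_a)
    mk_b = markers_for(bv, lb, classes_b)

    es_ab, p_ab, null_ab = _directional_pvalues(
        av, la, classes_a, bv, lb, classes_b, mk_a, n_perm, rng_b)
    es_ba_t, p_ba_t, null_ba = _directional_pvalues(
        bv, lb, classes_b, av, la, classes_a, mk_b, n_perm, rng_a)
    es_ba = es_ba_t.T       # align to (A, B) orientation
    p_ba = p_ba_t.T

    n_a, n_b = len(classes_a), len(classes_b)
    fisher = -2.0 * (np.log(p_ab) + np.log(p_ba))
    p_comb = np.empty((n_a, n_b))
    for i in range(n_a):
        for j in range(n_b):
            null_p_ab = _null_pvalues(null_ab[i, j])
            null_p_ba = _null_pvalues(null_ba[j, i])
            # per-cell generator keyed canonically so that swapping cohorts
            # transposes the result exactly
            ci, cj = (i, j) if a_first else (j, i)
            rng_f = np.random.default_rng(np.random.SeedSequence([seed, 7919, ci, cj]))
            draws = (null_p_ab, null_p_ba) if a_first else (null_p_ba, null_p_ab)
            p1 = draws[0][rng_f.integers(0, n_perm, size=n_fisher_null)]
            p2 = draws[1][rng_f.integers(0, n_perm, size=n_fisher_null)]
            f_null = -2.0 * (np.log(p1) + np.log(p2))
            p_comb[i, j] = (1 + int((f_null >= fisher[i, j]).sum())) / (n_fisher_null + 1)
    sa = bh_fdr(p_comb.ravel()).reshape(p_comb.shape)
    return SAMatrix(
        classes_a=classes_a, classes_b=classes_b, es_ab=es_ab, es_ba=es_ba,
        p_ab=p_ab, p_ba=p_ba, fisher=fisher, p_combined=p_comb, sa=sa,
    )


def _null_pvalues(null_es: np.ndarray) -> np.ndarray:
    """Add-one permutation p of each null ES against its own null distribution."""
    n = null_es.size
    sorted_desc = -np.sort(-null_es)
    counts = np.searchsorted(-sorted_desc, -null_es, side="right")  # #{null >= v}
    return counts / (n + 1.0)
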