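"""Supervised principal-component survival classification.

The procedure: screen genes by univariate Cox association with overall
survival (p < alpha on standardized expression), rank the survivors by
absolute Cox coefficient, compute principal components of the top-k gene
submatrix, fit a Cox model on the leading components and use its linear
predictor as the per-sample risk score.  Risk groups split at the median
score.  Honest significance comes from leave-one-out cross-validation in
which the *entire* pipeline — screening, ranking, PC extraction, Cox fit — is
rebuilt on every fold, and from a permutation test that repeats the whole
cross-validated procedure on survival data randomly reassigned to samples.

Cross-cohort marker pools are built by keeping, per cohort, the largest gene
set whose cross-validated split is significant at home and whose transferred
model splits every other cohort, then taking the union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix
from . import survstats
from .survstats import CoxError, TestResult

__all__ = [
    "SuperPCModel",
    "RiskAssignment",
    "PermutationResult",
    "GenePool",
    "screen_and_rank",
    "fit_superpc",
    "apply_model",
    "loocv_risk_groups",
    "permutation_pvalue",
    "cross_dataset_pool",
    "rank_model_genes",
    "nested_submodels",
]


@dataclass
class SuperPCModel:
    """Fitted supervised-PC survival model.

    ``loadings`` (genes x n_pc) have orthonormal columns; the risk score of a
    sample with standardized expression z is ``(z @ loadings) @ pc_coef``,
    oriented so that higher score means higher hazard.  ``gene_mean`` /
    ``gene_sd`` freeze the training standardization for transfer.
    """

    genes: list[str]
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    loadings: np.ndarray
    pc_coef: np.ndarray
    screened: pd.DataFrame               # screening table: coef, p per screened gene
    training_scores: pd.Series
    threshold: float
    alpha: float
    n_pc: int
    # training data retained so nested submodels can be refitted
    _train_values: np.ndarray | None = field(default=None, repr=False)
    _train_time: np.ndarray | None = field(default=None, repr=False)
    _train_event: np.ndarray | None = field(default=None, repr=False)

    @property
    def top_k(self) -> int:
        return len(self.genes)


@dataclass
class RiskAssignment:
    """Per-sample risk score and high/low group (high iff score > threshold)."""

    scores: pd.Series
    threshold: float

    @property
    def group(self) -> pd.Series:
        return pd.Series(
            np.where(self.scores.to_numpy() > self.threshold, "high", "low"),
            index=self.scores.index, name="group",
        )


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray

    @property
    def p_value(self) -> float:
        b = len(self.permuted)
        return (1 + int((self.permuted >= self.observed).sum())) / (b + 1)


@dataclass
class GenePool:
    """Union of per-cohort gene selections with provenance."""

    provenance: dict[str, set[str]]      # gene -> cohorts that selected it
    per_cohort: dict[str, list[str]]     # cohort -> its selected gene list

    @property
    def genes(self) -> list[str]:
        return sorted(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)


def _standardize_rows(v: np.ndarray):
    mean = v.mean(axis=1)
    sd = v.std(axis=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (v - mean[:, None]) / sd[:, None], mean, sd


def screen_and_rank(em: ExpressionMatrix, clinical: ClinicalTable,
                    alpha: float = 0.05, ties: str = "efron") -> pd.DataFrame:
    """Univariate Cox screen of every gene, ranked by |coefficient|.

    Expression is standardized per gene before fitting, so coefficients are
    log-hazards per SD.  Genes with p < ``alpha`` are kept and sorted by
    absolute coefficient (descending), ties broken by ascending p then gene
    id.  Returns a DataFrame indexed by gene with columns ``coef`` and ``p``
    (empty, with a warning, if nothing passes).
    """
    clin = clinical.aligned_to(em.sample_ids)
    z, _, _ = _standardize_rows(em.values)
    coef, _, p = survstats.cox_univariate_batch(z.T, clin.os_months, clin.event, ties=ties)
    tab = pd.DataFrame({"coef": coef, "p": p}, index=em.gene_ids)
    tab = tab[tab["p"] < alpha]
    if tab.empty:
        warnings.warn(f"no genes pass the univariate screen at alpha={alpha}")
        return tab
    tab = tab.assign(_abs=tab["coef"].abs(), _gene=tab.index)
    tab = tab.sort_values(["_abs", "p", "_gene"], ascending=[False, True, True])
    return tab.drop(columns=["_abs", "_gene"])


def _fit_core(values: np.ndarray, gene_ids: list[str], time, event,
              alpha: float, top_k: int, n_pc: int, ties: str = "efron"):
    """Shared screening + PC + Cox core; operates on raw arrays for speed."""
    z_all, _, _ = _standardize_rows(values)
    coef, _, p = survstats.cox_univariate_batch(z_all.T, time, event, ties=ties)
    passing = np.flatnonzero(p < alpha)
    if passing.size >= n_pc:
        order = passing[np.lexsort((np.asarray(gene_ids, dtype=object)[passing],
                                    p[passing], -np.abs(coef[passing])))]
        sel = order[:top_k]
    else:
        # degenerate fold: nothing (or too little) passes -- fall back to the
        # globally smallest p-values so the pipeline stays defined
        order = np.argsort(p, kind="stable")
        sel = order[:max(n_pc, min(top_k, len(order)))]
    if sel.size < n_pc:
        raise CoxError("fewer usable genes than requested components")

    sub = values[sel, :]
    zsub, mean, sd = _standardize_rows(sub)
    u_mat, s_vals, _ = np.linalg.svd(zsub, full_matrices=False)
    loadings = u_mat[:, :n_pc]
    scores = zsub.T @ loadings                      # samples x n_pc
    if n_pc == 1:
        b, _, _ = survstats.cox_univariate_batch(scores, time, event, ties=ties)
        pc_coef = b
    else:
        fit = survstats.fit_cox(scores, time, event, ties=ties)
        pc_coef = fit.coef
    risk = scores @ pc_coef
    screen_tab = pd.DataFrame(
        {"coef": coef[passing], "p": p[passing]},
        index=[gene_ids[i] for i in passing],
    )
    return sel, mean, sd, loadings, pc_coef, risk, screen_tab


def fit_superpc(em: ExpressionMatrix, clinical: ClinicalTable, top_k: int,
                n_pc: int = 1, alpha: float = 0.05, ties: str = "efron") -> SuperPCModel:
    """Fit the supervised-PC model on a training cohort.

    ``top_k`` screened genes feed the PCA; survival is regressed on the first
    ``n_pc`` components.  The stored threshold is the median training score
    (the cross-validation and transfer machinery may override it).
    """
    if top_k < n_pc:
        raise ValueError("top_k must be >= n_pc")
    clin = clinical.aligned_to(em.sample_ids)
    time, event = clin.os_months, clin.event
    sel, mean, sd, loadings, pc_coef, risk, screen_tab = _fit_core(
        em.values, em.gene_ids, time, event, alpha, top_k, n_pc, ties)
    genes = [em.gene_ids[i] for i in sel]
    scores = pd.Series(risk, index=em.sample_ids, name="risk_score")
    return SuperPCModel(
        genes=genes, gene_mean=mean, gene_sd=sd, loadings=loadings,
        pc_coef=np.atleast_1d(pc_coef), screened=screen_tab,
        training_scores=scores, threshold=float(np.median(risk)),
        alpha=alpha, n_pc=n_pc,
        _train_values=em.values[sel, :].copy(), _train_time=time.copy(),
        _train_event=event.copy(),
    )


def apply_model(model: SuperPCModel, em: ExpressionMatrix,
                threshold_source: str = "training",
                impute_mean: bool = False) -> RiskAssignment:
    """Score a new cohort with a frozen model.

    The new samples must already be on the same scale as training (batch
    co-adjusted).  Standardization, loadings and PC Cox coefficients all come
    from training; ``threshold_source`` chooses the training median
    (``"training"``, transfer "without further modification") or the new
    cohort's own median (``"cohort_median"``).
    """
    idx = {g: i for i, g in enumerate(em.gene_ids)}
    missing = [g for g in model.genes if g not in idx]
    if missing and not impute_mean:
        raise KeyError(f"model gene(s) absent from cohort: {missing}")
    if missing:
        warnings.warn(f"imputing training mean for absent gene(s): {missing}")
    z = np.zeros((len(model.genes), em.n_samples))
    for r, g in enumerate(model.genes):
        if g in idx:
            z[r] = (em.values[idx[g]] - model.gene_mean[r]) / model.gene_sd[r]
    risk = (z.T @ model.loadings) @ model.pc_coef
    scores = pd.Series(risk, index=em.sample_ids, name="risk_score")
    if threshold_source == "training":
        thr = model.threshold
    elif threshold_source == "cohort_median":
        thr = float(np.median(risk))
    else:
        raise ValueError(f"unknown threshold_source {threshold_source!r}")
    return RiskAssignment(scores=scores, threshold=thr)


def loocv_risk_groups(em: ExpressionMatrix, clinical: ClinicalTable,
                      alpha: float = 0.05, top_k: int = 19, n_pc: int = 1,
                      ties: str = "efron"):
    """Leave-one-out cross-validated risk groups and their log-rank test.

    Every fold re-runs the complete pipeline (screen, rank, PCs, Cox) on the
    other n-1 samples and scores the held-out sample with that fold's model;
    this removes the resubstitution optimism of scoring training data with a
    model that saw it.  Groups split at the median cross-validated score
    (ties to low risk).

    Returns ``(RiskAssignment, TestResult)``.  Note that the chi-square
    log-rank p on cross-validated groups retains some optimism when gene
    selection is survival-driven (each fold's screen reads the other n-1
    samples' outcomes, and the test couples all samples); honest significance
    of the split is the job of :func:`permutation_pvalue`.
    """
    clin = clinical.aligned_to(em.sample_ids)
    n = em.n_samples
    if n < 20:
        raise ValueError("LOOCV needs at least 20 samples")
    time, event = clin.os_months, clin.event
    values = em.values
    cv_scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if event[mask].sum() == 0:
            raise CoxError(f"fold holding out sample {em.sample_ids[i]!r} has no events")
        sel, mean, sd, loadings, pc_coef, _, _ = _fit_core(
            values[:, mask], em.gene_ids, time[mask], event[mask],
            alpha, top_k, n_pc, ties)
        # orient each fold consistently: higher score = higher hazard is
        # already guaranteed by the Cox coefficients entering the score
        z_i = (values[sel, i] - mean) / sd
        cv_scores[i] = float((z_i @ loadings) @ pc_coef)
        mask[i] = True
    thr = float(np.median(cv_scores))
    scores = pd.Series(cv_scores, index=em.sample_ids, name="risk_score")
    assignment = RiskAssignment(scores=scores, threshold=thr)
    groups = assignment.group.to_numpy()
    if len(np.unique(groups)) < 2:
        return assignment, TestResult(statistic=0.0, p_value=1.0, df=1)
    res = survstats.logrank_test(groups, time, event)
    return assignment, res


def permutation_pvalue(em: ExpressionMatrix, clinical: ClinicalTable,
                       alpha: float = 0.05, top_k: int = 19, n_pc: int = 1,
                       B: int = 100, seed: int = 0) -> PermutationResult:
    """Permutation significance of the cross-validated survival split.

    Survival records are randomly reassigned among samples and the entire
    cross-validated risk prediction is repeated ``B`` times; the p-value is
    the add-one fraction of permuted log-rank statistics at least as large as
    the observed one, testing the null of no relation between expression and
    survival.
    """
    if B < 20:
        raise ValueError("B must be >= 20")
    _, obs = loocv_risk_groups(em, clinical, alpha=alpha, top_k=top_k, n_pc=n_pc)
    rng = np.random.default_rng(seed)
    n = em.n_samples
    permuted = np.empty(B)
    clin = clinical.aligned_to(em.sample_ids)
    base = clin.data.copy()
    for b in range(B):
        perm = rng.permutation(n)
        shuffled = base.copy()
        shuffled["os_months"] = base["os_months"].to_numpy()[perm]
        shuffled["event"] = base["event"].to_numpy()[perm]
        _, res = loocv_risk_groups(em, ClinicalTable(shuffled), alpha=alpha,
                                   top_k=top_k, n_pc=n_pc)
        permuted[b] = res.statistic
    return PermutationResult(observed=obs.statistic, permuted=permuted)


def cross_dataset_pool(cohorts: dict[str, tuple[ExpressionMatrix, ClinicalTable]],
                       alpha: float = 0.05, n_pc: int = 1,
                       top_k_grid=(5, 10, 15, 20, 25, 30, 40, 50),
                       home_p: float = 0.05, transfer_p: float = 0.05,
                       threshold_source: str = "cohort_median") -> GenePool:
    """Cross-dataset marker-pool construction.

    For each cohort, supervised-PC models are fitted over a grid of top-k
    sizes; the cohort contributes the *largest* gene set whose leave-one-out
    split is significant at home AND whose frozen model, transferred to every
    other cohort, splits that cohort's survival significantly.  The pool is
    the union of the per-cohort selections, with provenance.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    per_cohort: dict[str, list[str]] = {}
    for name, (em, clin) in cohorts.items():
        best: list[str] | None = None
        for top_k in sorted(top_k_grid):
            try:
                _, res = loocv_risk_groups(em, clin, alpha=alpha, top_k=top_k, n_pc=n_pc)
            except (CoxError, ValueError):
                continue
            if res.p_value >= home_p:
                continue
            model = fit_superpc(em, clin, top_k=top_k, n_pc=n_pc, alpha=alpha)
            ok = True
            for other, (em_o, clin_o) in cohorts.items():
                if other == name:
                    continue
                try:
                    ra = apply_model(model, em_o, threshold_source=threshold_source)
                    grp = ra.group.to_numpy()
                    if len(np.unique(grp)) < 2:
                        ok = False
                        break
                    clin_al = clin_o.aligned_to(em_o.sample_ids)
                    res_o = survstats.logrank_test(grp, clin_al.os_months, clin_al.event)
                except (CoxError, ValueError):
                    ok = False
                    break
                if res_o.p_value >= transfer_p:
                    ok = False
                    break
            if ok:
                best = list(model.genes)
        if best is not None:
            per_cohort[name] = best
    if not per_cohort:
        warnings.warn("no cohort yielded a significant transferable model; pool is empty")
    provenance: dict[str, set[str]] = {}
    for name, genes in per_cohort.items():
        for g in genes:
            provenance.setdefault(g, set()).add(name)
    return GenePool(provenance=provenance, per_cohort=per_cohort)


def rank_model_genes(model: SuperPCModel) -> pd.Series:
    """Model genes ordered by contribution weight.

    Weight of gene g = sum over used components of |loading_gc x PC Cox
    coefficient_c|; returned descending.
    """
    w = np.abs(model.loadings * model.pc_coef[None, :]).sum(axis=1)
    s = pd.Series(w, index=model.genes, name="weight")
    return s.sort_values(ascending=False, kind="stable")


def nested_submodels(model: SuperPCModel, m: int) -> SuperPCModel:
    """Refit the model on its top-m genes by contribution weight."""
    if m < model.n_pc:
        raise ValueError("m must be >= the number of components")
    if m > model.top_k:
        raise ValueError("m cannot exceed the model's gene count")
    if model._train_values is None:
        raise ValueError("model carries no training data; refit is impossible")
    ranked = list(rank_model_genes(model).index)[:m]
    gidx = {g: i for i, g in enumerate(model.genes)}
    rows = [gidx[g] for g in ranked]
    sub_vals = model._train_values[rows, :]
    time, event = model._train_time, model._train_event
    zsub, mean, sd = _standardize_rows(sub_vals)
    u_mat, _, _ = np.linalg.svd(zsub, full_matrices=False)
    loadings = u_mat[:, :model.n_pc]
    scores = zsub.T @ loadings
    if model.n_pc == 1:
        b, _, _ = survstats.cox_univariate_batch(scores, time, event)
        pc_coef = b
    else:
        pc_coef = survstats.fit_cox(scores, time, event).coef
    risk = scores @ pc_coef
    return SuperPCModel(
        genes=ranked, gene_mean=mean, gene_sd=sd, loadings=loadings,
        pc_coef=np.atleast_1d(pc_coef), screened=model.screened,
        training_scores=pd.Series(risk, index=model.training_scores.index,
                                  name="risk_score"),
        threshold=float(np.median(risk)), alpha=model.alpha, n_pc=model.n_pc,
        _train_values=sub_vals.copy(), _train_time=time, _train_event=event,
    )
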