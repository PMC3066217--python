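"""Synthetic validation studies exercising the full pipeline.

Each function simulates data with known ground truth, runs the corresponding
pipeline stage(s) end to end and returns the measured quantities.  They are
consumed by the acceptance test suite and by ``scripts/acceptance.py``; all
randomness is controlled by the ``seed`` argument.

Problem sizes are fixed study designs: the integration study uses the
4-batch x 60-sample, 2000-gene default; supervised-PC studies run at the
650-gene marker-pool scale with 240 training samples; cross-cohort pools use
three 100-sample cohorts sharing 30 prognostic genes.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import integrate, oncoprobit, pathways, sigmodel, submap, survstats, synthdata
from .datatypes import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .synthdata import SimulationConfig

__all__ = [
    "batch_adjustment_study",
    "loocv_null_calibration",
    "signal_recovery_study",
    "pool_study",
    "submap_study",
    "oracle_equivalence",
    "gsa_study",
    "probit_study",
]


def _nearest_centroid_cv_accuracy(values, labels, n_folds=5, seed=0):
    """5-fold cross-validated nearest-centroid classification accuracy."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = values.shape[1]
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    classes = np.unique(labels)
    correct = 0
    for fold in folds:
        train = np.setdiff1d(order, fold)
        cents = np.stack([values[:, train[labels[train] == c]].mean(axis=1)
                          for c in classes], axis=1)
        d = ((values[:, fold, None] - cents[:, None, :]) ** 2).sum(axis=0)
        pred = classes[np.argmin(d, axis=1)]
        correct += (pred == labels[fold]).sum()
    return correct / n


def batch_adjustment_study(seed: int = 0) -> dict:
    """Batch-effect recovery: classifier accuracy before/after adjustment and
    preservation of a planted biological group difference declared as
    covariate."""
    cfg = SimulationConfig(n_batches=4, samples_per_batch=60, n_genes=2000,
                           gamma_sd=2.0, n_subclasses=2, subclass_effect=1.0,
                           seed=seed)
    em, clinical, truth = synthdata.simulate_integration_study(cfg)
    acc_pre = _nearest_centroid_cv_accuracy(em.values, em.batch, seed=seed)
    group = (truth.subclass == "C1").astype(float)
    adj, _ = integrate.combat_adjust(em, covariates=group)
    acc_post = _nearest_centroid_cv_accuracy(adj.values, adj.batch, seed=seed)

    marker_rows = [em.gene_ids.index(g) for g in truth.subclass_marker_ids["C1"]]
    diff = (adj.values[np.ix_(marker_rows, np.flatnonzero(group == 1))].mean()
            - adj.values[np.ix_(marker_rows, np.flatnonzero(group == 0))].mean())
    rel_err = abs(diff - cfg.subclass_effect) / cfg.subclass_effect
    return {"accuracy_pre": float(acc_pre), "accuracy_post": float(acc_post),
            "covariate_relative_error": float(rel_err), "n": em.n_samples}


def loocv_null_calibration(seed: int = 0, n_sims: int = 100) -> dict:
    """Rejection rate of the LOOCV log-rank p at 0.05 on no-signal studies
    (n=100, 1000 genes)."""
    rejections = 0
    for k in range(n_sims):
        cfg = SimulationConfig(n_batches=1, samples_per_batch=100, n_genes=1000,
                               n_prognostic=1, beta=0.0, gamma_sd=0.0,
                               delta_shape=0.0, subclass_effect=0.0,
                               seed=seed * 100000 + k)
        em, clinical, _ = synthdata.simulate_integration_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, res = sigmodel.loocv_risk_groups(em, clinical, alpha=0.05, top_k=19)
        rejections += res.p_value < 0.05
    return {"rejection_rate": rejections / n_sims, "n": n_sims}


def signal_recovery_study(seed: int = 0, B: int = 50) -> dict:
    """Planted-signal study at the marker-pool scale: screening recall,
    LOOCV split, permutation significance and model transfer."""
    cfg = SimulationConfig(n_batches=1, samples_per_batch=240, n_genes=650,
                           n_prognostic=20, beta=0.8, gamma_sd=0.0,
                           delta_shape=0.0, seed=seed)
    em, clinical, truth = synthdata.simulate_integration_study(cfg)
    tab = sigmodel.screen_and_rank(em, clinical, alpha=0.05)
    recovered = len(set(truth.prognostic_gene_ids) & set(tab.index))

    _, loocv_res = sigmodel.loocv_risk_groups(em, clinical, alpha=0.05, top_k=19)
    perm = sigmodel.permutation_pvalue(em, clinical, alpha=0.05, top_k=19,
                                       B=B, seed=seed + 1)

    model = sigmodel.fit_superpc(em, clinical, top_k=19)
    cfg_v = SimulationConfig(n_batches=1, samples_per_batch=120, n_genes=650,
                             n_prognostic=20, beta=0.8, gamma_sd=0.0,
                             delta_shape=0.0, seed=seed + 7919)
    em_v, clin_v, _ = synthdata.simulate_integration_study(cfg_v)
    ra = sigmodel.apply_model(model, em_v, threshold_source="cohort_median")
    grp = ra.group.to_numpy()
    res_v = survstats.logrank_test(grp, clin_v.os_months, clin_v.event)
    hr_fit = survstats.fit_cox((grp == "high").astype(float), clin_v.os_months,
                               clin_v.event)
    km = survstats.km_estimate(clin_v.os_months, clin_v.event, grp)
    return {
        "screen_recovered": int(recovered),
        "loocv_logrank_p": float(loocv_res.p_value),
        "permutation_p": float(perm.p_value),
        "transfer_logrank_p": float(res_v.p_value),
        "transfer_hr": float(hr_fit.hr[0]),
        "transfer_median_os_high": km["high"].median,
        "transfer_median_os_low": km["low"].median,
        "n": em.n_samples,
    }


def pool_study(seed: int = 0) -> dict:
    """Cross-dataset marker pool over three cohorts sharing 30 planted
    prognostic genes."""
    cohorts = {}
    truths = {}
    for i in range(3):
        cfg = SimulationConfig(n_batches=1, samples_per_batch=100, n_genes=1000,
                               n_prognostic=30, beta=0.9, gamma_sd=0.0,
                               delta_shape=0.0, seed=seed * 1000 + i)
        em, clin, truth = synthdata.simulate_integration_study(cfg)
        cohorts[f"cohort{i}"] = (em, clin)
        truths[f"cohort{i}"] = truth
    pool = sigmodel.cross_dataset_pool(cohorts, top_k_grid=(5, 10, 15, 20, 25, 30, 40))
    planted = set(next(iter(truths.values())).prognostic_gene_ids)
    all_genes = set(next(iter(cohorts.values()))[0].gene_ids)
    noise = all_genes - planted
    got = set(pool.genes)
    union = set().union(*pool.per_cohort.values()) if pool.per_cohort else set()
    return {
        "planted_recall": len(got & planted) / len(planted),
        "noise_fraction": len(got & noise) / len(noise),
        "union_consistent": float(got == union),
        "pool_size": len(got),
        "n": sum(em.n_samples for em, _ in cohorts.values()),
    }


def submap_study(seed: int = 0, n_perm: int = 200, n_null_runs: int = 50) -> dict:
    """Subclass-mapping behavior: self-correspondence, matched independent
    pair, and the label-permutation runs."""
    cfg = SimulationConfig(n_batches=1, samples_per_batch=100, n_genes=600,
                           n_subclasses=2, subclass_effect=1.5,
                           markers_per_subclass=50, seed=seed)
    (a, la), (b, lb), _ = synthdata.simulate_subclass_pair(cfg)

    sa_self = submap.run_submap(a, la, a, la, m=50, n_perm=n_perm, seed=seed)
    sa_pair = submap.run_submap(a, la, b, lb, m=50, n_perm=n_perm, seed=seed)

    rng = np.random.default_rng(seed + 1)
    clean = 0
    for k in range(n_null_runs):
        lb_perm = list(rng.permutation(lb))
        sa = submap.run_submap(a, la, b, lb_perm, m=50, n_perm=n_perm,
                               seed=seed + 2 + k)
        clean += not (sa.sa < 0.05).any()
    off = ~np.eye(2, dtype=bool)
    return {
        "self_diag_max_fdr": float(np.diag(sa_self.sa).max()),
        "self_offdiag_min_fdr": float(sa_self.sa[off].min()),
        "pair_diag_max_fdr": float(np.diag(sa_pair.sa).max()),
        "pair_offdiag_min_fdr": float(sa_pair.sa[off].min()),
        "permuted_clean_fraction": clean / n_null_runs,
        "n": a.n_samples,
    }


def _enumerate_fisher_p(a, b, c, d):
    r1, c1, n = a + b, a + c, a + b + c + d
    kmin, kmax = max(0, c1 - (c + d)), min(r1, c1)
    probs = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(kmin, kmax + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def oracle_equivalence(seed: int = 0, logrank_B: int = 10000) -> dict:
    """Agreement of the statistics engine with independent oracles.

    Fisher vs exhaustive enumeration on all tables with margins <= 12; Cox
    vs grid-search maximization of the hand-coded partial likelihood; EASE
    vs direct hypergeometric summation; log-rank chi-square p vs a
    10,000-draw permutation oracle on fixed n=30 fixtures.
    """
    fisher_max = 0.0
    for a in range(13):
        for b in range(13 - a):
            for c in range(13):
                for d in range(13 - c):
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    mine = survstats.fisher_exact([[a, b], [c, d]]).p_value
                    fisher_max = max(fisher_max, abs(mine - _enumerate_fisher_p(a, b, c, d)))

    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 1, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0])

    def pll(beta):
        out = 0.0
        for i in range(4):
            risk = time >= time[i]
            out += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return out

    grid = np.linspace(-5, 5, 2000001)
    beta_grid = grid[int(np.argmax([pll(bb) for bb in grid[::100]])) * 100]
    fine = np.linspace(beta_grid - 0.01, beta_grid + 0.01, 200001)
    beta_grid = fine[int(np.argmax([pll(bb) for bb in fine]))]
    fit = survstats.fit_cox(x, time, event)
    cox_diff = abs(fit.coef[0] - beta_grid)

    ease_max = 0.0
    bg = [f"g{i}" for i in range(100)]
    cat = bg[:20]
    hits = cat[:5] + bg[20:25]
    res = pathways.ease_analysis(hits, bg, GeneSetCollection({"cat": cat}))
    oracle = sum(stats.hypergeom.pmf(k, 100, 20, 10) for k in range(4, 11))
    ease_max = max(ease_max, abs(res.loc["cat", "ease_score"] - oracle))

    # log-rank vs permutation oracle on fixtures prespecified by seed index
    logrank_gap_units = []
    for fix_seed in range(4):
        rng = np.random.default_rng(fix_seed)
        n = 30
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.8).astype(int)
        g = np.array(["a"] * 15 + ["b"] * 15)
        t[:15] *= rng.uniform(0.5, 1.0)
        obs = survstats.logrank_test(g, t, e)
        prng = np.random.default_rng(seed + 100 + fix_seed)
        exceed = 0
        for _ in range(logrank_B):
            gp = prng.permutation(g)
            exceed += survstats.logrank_test(gp, t, e).statistic >= obs.statistic - 1e-12
        p_perm = exceed / logrank_B
        mc_se = max(np.sqrt(p_perm * (1 - p_perm) / logrank_B), 1e-6)
        logrank_gap_units.append(abs(obs.p_value - p_perm) / mc_se)
    return {
        "fisher_max_abs_diff": float(fisher_max),
        "cox_grid_abs_diff": float(cox_diff),
        "ease_max_abs_diff": float(ease_max),
        "logrank_max_gap_mc_se_units": float(max(logrank_gap_units)),
        "n": logrank_B,
    }


def gsa_study(seed: int = 0, n_null_runs: int = 20, n_power_runs: int = 20) -> dict:
    """Gene-set analysis calibration (random sets, null data) and power
    (30-gene set shifted +1 SD at n=50/50)."""
    total = hits = 0
    for k in range(n_null_runs):
        rng = np.random.default_rng(seed * 5000 + k)
        G = 1000
        vals = rng.normal(0, 1, (G, 100))
        em = ExpressionMatrix([f"g{i}" for i in range(G)],
                              [f"s{j}" for j in range(100)], vals)
        labels = ["hi"] * 50 + ["lo"] * 50
        gsc = GeneSetCollection({
            f"set{t}": list(rng.choice(em.gene_ids, size=30, replace=False))
            for t in range(25)
        })
        res = pathways.gsa(em, labels, gsc, n_perm=200, seed=k)
        hits += int((res.table["p"] < 0.05).sum())
        total += len(res.table)

    detected = 0
    for k in range(n_power_runs):
        rng = np.random.default_rng(seed * 7000 + k)
        G = 1000
        vals = rng.normal(0, 1, (G, 100))
        vals[:30, :50] += 1.0
        em = ExpressionMatrix([f"g{i}" for i in range(G)],
                              [f"s{j}" for j in range(100)], vals)
        labels = ["hi"] * 50 + ["lo"] * 50
        gsc = GeneSetCollection({
            "planted": [f"g{i}" for i in range(30)],
            **{f"set{t}": list(rng.choice(em.gene_ids[30:], size=30, replace=False))
               for t in range(10)},
        })
        res = pathways.gsa(em, labels, gsc, n_perm=200, seed=k)
        detected += res.table.loc["planted", "p"] < 0.05
    return {
        "null_fp_rate": hits / total,
        "power": detected / n_power_runs,
        "n": total,
    }


def probit_study(seed: int = 0, n_runs: int = 20) -> dict:
    """Pathway-activation scoring: held-out accuracy at separation 3,
    monotonicity along the off-to-on mixture path, and odds-ratio recovery
    when activation is planted to co-occur with high risk at OR = 3."""
    correct = total = 0
    monotone_ok = 0
    for k in range(n_runs):
        em, labels = synthdata.simulate_pathway_training(20, 20, 60, 3.0,
                                                         seed=seed * 900 + k)
        ids = np.asarray(em.sample_ids)
        on = np.asarray(labels) == "on"
        train_idx = np.r_[np.arange(0, 12), np.arange(20, 32)]
        test_idx = np.r_[np.arange(12, 20), np.arange(32, 40)]
        x_on = em.subset_samples(ids[train_idx][on[train_idx]])
        x_off = em.subset_samples(ids[train_idx][~on[train_idx]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = oncoprobit.train_signature(x_on, x_off, n_genes=60,
                                             n_mc=1000, burn_in=300,
                                             seed=seed * 900 + k)
        calls = oncoprobit.predict_activation(sig, em.subset_samples(ids[test_idx]))
        correct += (calls.call.to_numpy() == on[test_idx]).sum()
        total += len(test_idx)

        c_on = x_on.values.mean(axis=1)
        c_off = x_off.values.mean(axis=1)
        ts = np.linspace(0, 1, 11)
        mix = np.stack([c_off * (1 - t) + c_on * t for t in ts], axis=1)
        tum = ExpressionMatrix(x_on.gene_ids, [f"m{j}" for j in range(11)], mix)
        prob = oncoprobit.predict_activation(sig, tum).probability.to_numpy()
        monotone_ok += bool((np.diff(prob) >= -1e-9).all())

    or_estimates = []
    for k in range(n_runs):
        rng = np.random.default_rng(seed * 1100 + k)
        n = 240
        high = rng.random(n) < 0.5
        p0 = 0.35
        odds1 = 3.0 * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        act = np.where(high, rng.random(n) < p1, rng.random(n) < p0)
        ids = [f"s{i}" for i in range(n)]
        calls = oncoprobit.ActivationCall(
            probability=pd.Series(np.where(act, 0.9, 0.1), index=ids))
        risk = pd.Series(np.where(high, "high", "low"), index=ids)
        orr, _, _ = oncoprobit.risk_pathway_association(calls, risk)
        or_estimates.append(orr)
    return {
        "holdout_accuracy": correct / total,
        "monotone_fraction": monotone_ok / n_runs,
        "or_median": float(np.median(or_estimates)),
        "n": total,
    }
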