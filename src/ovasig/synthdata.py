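"""Synthetic multi-cohort expression studies with known ground truth.

The generator emulates the structure of a multi-institution microarray
meta-analysis: several batches (cohorts) measured on a shared gene space with
additive and multiplicative per-gene batch effects, a planted prognostic gene
program whose latent score drives exponential survival with independent
administrative censoring, discrete molecular subclasses with marker-gene
programs, and on/off pathway-activation training arrays.

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ClinicalTable, ExpressionMatrix
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_integration_study",
    "simulate_subclass_pair",
    "simulate_pathway_training",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_integration_study`.

    Defaults mirror a four-cohort advanced-stage ovarian-cancer meta-analysis
    at desk scale: 4 batches of 60 arrays, 2000 genes of which 20 carry the
    prognostic program, a log-hazard of 0.8 per SD of the latent risk score,
    a constant baseline hazard of 0.02 events/month (median OS near 35
    months) and ~30% administrative censoring.
    """

    n_batches: int = 4
    samples_per_batch: int = 60
    n_genes: int = 2000
    n_prognostic: int = 20
    beta: float = 0.8                  # log-hazard per SD of the latent score
    gamma_sd: float = 2.0              # SD of additive per-gene batch shifts (log2 units)
    delta_shape: float = 0.3           # dispersion of multiplicative per-gene batch scale
    baseline_hazard: float = 0.02      # events per month
    censor_rate: float = 0.3           # target administrative-censoring fraction
    n_subclasses: int = 2
    subclass_effect: float = 1.0       # mean shift of subclass marker genes (log2 units)
    noise_sd: float = 0.5              # residual per-gene noise SD
    markers_per_subclass: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_batches", "samples_per_batch", "n_genes", "n_prognostic",
                     "n_subclasses"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.n_prognostic > self.n_genes:
            raise ValueError("n_prognostic cannot exceed n_genes")
        if self.delta_shape < 0:
            raise ValueError("delta_shape must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    prognostic_gene_ids: list[str]
    latent_score: np.ndarray            # per sample, standardized
    gamma: np.ndarray                   # additive batch effect, genes x batches
    delta: np.ndarray                   # multiplicative noise scale, genes x batches
    subclass: np.ndarray                # per-sample subclass label (str)
    subclass_marker_ids: dict[str, list[str]] = field(default_factory=dict)
    pathway_state: np.ndarray | None = None
    censor_horizon: float | None = None


def _censor_horizon(event_times: np.ndarray, target: float) -> float:
    """Solve for the uniform-censoring horizon tau with P(C < T) = target.

    With C ~ U(0, tau) independent of T, a sample with event time T_i is
    censored with probability min(T_i / tau, 1); the marginal censoring
    fraction averaged over the realized event times is monotone decreasing
    in tau and is solved by bisection.
    """
    if target <= 0:
        return float(np.inf)

    def frac(tau):
        return float(np.mean(np.minimum(event_times / tau, 1.0)))

    lo, hi = 1e-6, float(event_times.max()) * 2 + 1e-6
    while frac(hi) > target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_integration_study(config: SimulationConfig):
    """Simulate one multi-batch expression study with survival ground truth.

    Expression model per gene g, sample j in batch i::

        x_gj = alpha_g + subclass shift + b_g * u_j + gamma_gi + delta_gi * eps_gj

    where ``u_j ~ N(0,1)`` is the latent risk score, ``b_g = +/-1`` for the
    ``n_prognostic`` planted genes (0 otherwise), ``gamma_gi ~ N(0,
    gamma_sd^2)``, ``delta_gi = exp(N(0, delta_shape^2))`` and ``eps ~ N(0,
    noise_sd^2)``.  Survival times are exponential with hazard
    ``baseline_hazard * exp(beta * u_j)``; censoring is independent uniform
    administrative censoring with a numerically calibrated horizon.

    Returns ``(ExpressionMatrix, ClinicalTable, SyntheticTruth)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_batches * cfg.samples_per_batch
    G = cfg.n_genes

    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    batches = np.repeat([f"B{i}" for i in range(cfg.n_batches)], cfg.samples_per_batch)

    alpha = rng.normal(7.0, 1.0, size=G)
    u = rng.standard_normal(n)
    u = (u - u.mean()) / u.std()

    loadings = np.zeros(G)
    prog_idx = np.arange(cfg.n_prognostic)
    signs = np.where(np.arange(cfg.n_prognostic) % 2 == 0, 1.0, -1.0)
    loadings[prog_idx] = signs

    # subclasses assigned within batch so batches stay balanced
    sub = np.empty(n, dtype=object)
    for b in range(cfg.n_batches):
        lab = np.array([f"C{k + 1}" for k in range(cfg.n_subclasses)])
        block = np.resize(lab, cfg.samples_per_batch)
        rng.shuffle(block)
        sub[b * cfg.samples_per_batch:(b + 1) * cfg.samples_per_batch] = block

    marker_ids: dict[str, list[str]] = {}
    sub_shift = np.zeros((G, n))
    start = cfg.n_prognostic
    for k in range(cfg.n_subclasses):
        name = f"C{k + 1}"
        idx = np.arange(start, min(start + cfg.markers_per_subclass, G))
        start += cfg.markers_per_subclass
        marker_ids[name] = [gene_ids[i] for i in idx]
        member = (sub == name)
        sub_shift[np.ix_(idx, np.flatnonzero(member))] = cfg.subclass_effect

    gamma = rng.normal(0.0, cfg.gamma_sd, size=(G, cfg.n_batches))
    delta = np.exp(rng.normal(0.0, cfg.delta_shape, size=(G, cfg.n_batches)))
    batch_idx = np.repeat(np.arange(cfg.n_batches), cfg.samples_per_batch)

    eps = rng.normal(0.0, cfg.noise_sd, size=(G, n))
    values = (
        alpha[:, None]
        + sub_shift
        + loadings[:, None] * u[None, :]
        + gamma[:, batch_idx]
        + delta[:, batch_idx] * eps
    )

    hazard = cfg.baseline_hazard * np.exp(cfg.beta * u)
    t_event = rng.exponential(1.0 / hazard)
    tau = _censor_horizon(t_event, cfg.censor_rate)
    if np.isinf(tau):
        os_months, event = t_event, np.ones(n, dtype=int)
    else:
        c = rng.uniform(0.0, tau, size=n)
        event = (t_event <= c).astype(int)
        os_months = np.minimum(t_event, c)

    em = ExpressionMatrix(gene_ids, sample_ids, values, batch=list(batches))
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "os_months": os_months,
        "event": event,
        "age_years": np.round(rng.uniform(40, 80, size=n), 1),
        "stage": rng.choice([3, 4], size=n, p=[0.85, 0.15]),
        "grade": rng.choice([2, 3], size=n, p=[0.3, 0.7]),
        "debulking": rng.choice(["optimal", "suboptimal"], size=n),
        "histology": "serous",
        "subtype": sub.astype(str),
    }))
    truth = SyntheticTruth(
        prognostic_gene_ids=[gene_ids[i] for i in prog_idx],
        latent_score=u,
        gamma=gamma,
        delta=delta,
        subclass=sub.astype(str),
        subclass_marker_ids=marker_ids,
        censor_horizon=None if np.isinf(tau) else float(tau),
    )
    return em, clinical, truth


def simulate_subclass_pair(config: SimulationConfig):
    """Two independent cohorts sharing the same planted subclass programs.

    Both cohorts plant identical marker-gene programs (same genes, same
    shift) on independent noise backgrounds; the ground-truth correspondence
    between their subclasses is the identity pairing.  Subclass occupancies
    are balanced; a configuration that would leave any subclass below 10% of
    a cohort is rejected.

    Returns ``((ExpressionMatrix, labels_a), (ExpressionMatrix, labels_b),
    marker_ids)``.
    """
    cfg = config
    if cfg.n_subclasses < 2:
        raise ValueError("need at least 2 subclasses")
    n = cfg.n_batches * cfg.samples_per_batch
    if 1.0 / cfg.n_subclasses < 0.10:
        raise ValueError(
            "balanced design would place a subclass below 10% occupancy; "
            "use fewer subclasses"
        )
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]
    lab_names = [f"C{k + 1}" for k in range(cfg.n_subclasses)]
    marker_ids = {}
    start = 0
    blocks = {}
    for name in lab_names:
        idx = np.arange(start, min(start + cfg.markers_per_subclass, G))
        start += cfg.markers_per_subclass
        marker_ids[name] = [gene_ids[i] for i in idx]
        blocks[name] = idx

    def one_cohort(tag: str):
        labels = np.resize(np.array(lab_names, dtype=object), n)
        rng.shuffle(labels)
        alpha = rng.normal(7.0, 1.0, size=G)
        vals = alpha[:, None] + rng.normal(0.0, 1.0, size=(G, n))
        for name in lab_names:
            member = np.flatnonzero(labels == name)
            vals[np.ix_(blocks[name], member)] += cfg.subclass_effect
        sample_ids = [f"{tag}{j:04d}" for j in range(n)]
        return ExpressionMatrix(gene_ids, sample_ids, vals), [str(x) for x in labels]

    cohort_a = one_cohort("A")
    cohort_b = one_cohort("B")
    return cohort_a, cohort_b, marker_ids


def simulate_pathway_training(n_on: int, n_off: int, n_sig_genes: int,
                              separation: float, seed: int,
                              n_genes: int = 1000):
    """On/off pathway-activation training arrays.

    The first ``n_sig_genes`` genes are shifted by ``separation`` noise-SDs in
    the "on" arrays; all other genes are pure noise.  Returns
    ``(ExpressionMatrix, labels)`` with labels in ``{"on", "off"}``.
    """
    if n_on < 5 or n_off < 5:
        raise ValueError("need at least 5 arrays per class")
    if n_sig_genes > n_genes:
        raise ValueError("n_sig_genes cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n = n_on + n_off
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"P{j:04d}" for j in range(n)]
    labels = ["on"] * n_on + ["off"] * n_off
    alpha = rng.normal(7.0, 1.0, size=n_genes)
    vals = alpha[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n))
    vals[:n_sig_genes, :n_on] += separation
    return ExpressionMatrix(gene_ids, sample_ids, vals), labels
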