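import warnings

import numpy as np
import pytest
from scipy import stats

from ovasig import integrate, synthdata
from ovasig.datatypes import IdMap, ValidationError
from ovasig.synthdata import SimulationConfig

from conftest import make_clinical, make_matrix


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        em = make_matrix(np.tile([[1.0], [5.0], [3.0]], (1, 4)))
        out = integrate.quantile_normalize(em)
        assert np.allclose(out.values, em.values)

    def test_two_column_average_of_order_statistics(self):
        em = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = integrate.quantile_normalize(em)
        assert np.allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_columns_share_sorted_vector_and_ranks_preserved(self, rng):
        em = make_matrix(rng.normal(7, 2, (50, 6)))
        out = integrate.quantile_normalize(em)
        ref = np.sort(out.values[:, 0])
        for j in range(6):
            assert np.allclose(np.sort(out.values[:, j]), ref)
            assert np.array_equal(np.argsort(out.values[:, j]),
                                  np.argsort(em.values[:, j]))

    def test_single_sample_warns_and_returns_input(self):
        em = make_matrix([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="single-sample"):
            out = integrate.quantile_normalize(em)
        assert out == em


class TestRLE:
    def test_identical_arrays_no_flags(self):
        em = make_matrix(np.tile([[5.0], [6.0], [7.0], [8.0]], (1, 5)))
        qc = integrate.rle_outlier_flags(em)
        assert qc.outlier_flags == []
        assert np.allclose(qc.rle_median, 0.0)

    def test_globally_shifted_array_flagged(self, rng):
        vals = rng.normal(7, 1, (200, 21))
        vals[:, 13] += 3.0
        em = make_matrix(vals)
        qc = integrate.rle_outlier_flags(em)
        assert "s13" in qc.outlier_flags
        assert qc.rle_median["s13"] == pytest.approx(3.0, abs=0.3)

    def test_clean_simulated_arrays_rarely_flagged(self):
        cfg = SimulationConfig(n_batches=1, samples_per_batch=100, n_genes=500,
                               gamma_sd=0.0, delta_shape=0.0, seed=2)
        em, _, _ = synthdata.simulate_integration_study(cfg)
        qc = integrate.rle_outlier_flags(em)
        assert len(qc.outlier_flags) <= 5


class TestMapAndMerge:
    def test_identical_namespaces_full_intersection(self, rng):
        a = make_matrix(rng.normal(size=(4, 3)), prefix_s="a")
        b = make_matrix(rng.normal(size=(4, 2)), prefix_s="b")
        merged = integrate.map_and_merge({"A": a, "B": b})
        assert merged.gene_ids == a.gene_ids
        assert merged.batch == ["A"] * 3 + ["B"] * 2

    def test_mapped_intersection(self, rng):
        a = make_matrix(rng.normal(size=(3, 2)), prefix_s="a")   # g0 g1 g2
        b = make_matrix(rng.normal(size=(3, 2)), prefix_g="p", prefix_s="b")
        idmap = IdMap.from_pairs([("p0", "g0"), ("p1", "g1"), ("p2", "g9")])
        merged = integrate.map_and_merge({"A": a, "B": b}, idmap)
        assert merged.gene_ids == ["g0", "g1"]

    def test_collapse_mean_averages_probes(self):
        a = make_matrix([[1.0, 3.0], [5.0, 7.0], [10.0, 20.0]], prefix_g="p", prefix_s="a")
        idmap = IdMap.from_pairs([("p0", "g"), ("p1", "g"), ("p2", "h")])
        merged = integrate.map_and_merge({"A": a}, idmap)
        row = merged.values[merged.gene_ids.index("g")]
        assert np.allclose(row, [3.0, 5.0])

    def test_collapse_max_var_keeps_most_variable_probe(self):
        a = make_matrix([[1.0, 1.1], [0.0, 9.0]], prefix_g="p", prefix_s="a")
        idmap = IdMap.from_pairs([("p0", "g"), ("p1", "g")])
        merged = integrate.map_and_merge({"A": a}, idmap, collapse="max_var")
        assert np.allclose(merged.values[0], [0.0, 9.0])

    def test_empty_intersection_names_cohorts(self, rng):
        a = make_matrix(rng.normal(size=(2, 2)), prefix_g="x", prefix_s="a")
        b = make_matrix(rng.normal(size=(2, 2)), prefix_g="y", prefix_s="b")
        with pytest.raises(ValidationError, match="'A'.*'B'"):
            integrate.map_and_merge({"A": a, "B": b})


class TestRV:
    def test_self_rv_is_one(self, rng):
        x = rng.normal(size=(30, 12))
        assert integrate.rv_coefficient(x, x) == pytest.approx(1.0)

    def test_orthonormal_gene_rotation_invariance(self, rng):
        x = rng.normal(size=(30, 12))
        q, _ = np.linalg.qr(rng.normal(size=(30, 30)))
        assert integrate.rv_coefficient(x, q @ x) == pytest.approx(1.0, abs=1e-10)

    def test_independent_matrices_low_modified_rv(self):
        """Unrelated Gaussian matrices: the diagonal-corrected RV stays near
        zero (the classical RV is biased to ~1/(1+n/G) here by construction,
        so the null check uses the modified form)."""
        vals = []
        classical = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            a, b = r.normal(size=(200, 50)), r.normal(size=(200, 50))
            vals.append(integrate.rv_coefficient(a, b, modified=True))
            classical.append(integrate.rv_coefficient(a, b))
        assert np.quantile(vals, 0.99) < 0.2
        # classical RV sits near its analytic noise floor 1/(1 + n/G) = 0.8
        assert np.median(classical) == pytest.approx(0.8, abs=0.05)

    def test_modified_rv_self_is_one(self, rng):
        x = rng.normal(size=(30, 12))
        assert integrate.rv_coefficient(x, x, modified=True) == pytest.approx(1.0)

    def test_symmetry_and_range(self, rng):
        x = rng.normal(size=(40, 15))
        y = x + rng.normal(scale=0.5, size=(40, 15))
        rxy = integrate.rv_coefficient(x, y)
        assert rxy == pytest.approx(integrate.rv_coefficient(y, x), abs=1e-12)
        assert 0.0 <= rxy <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            integrate.rv_coefficient(np.ones((5, 4)), np.random.default_rng(0).normal(size=(5, 4)))


class TestMDS:
    def test_planar_points_recovered_up_to_isometry(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
        em = make_matrix(pts.T)  # 2 "genes" = coordinates, 4 samples
        coords = integrate.classical_mds(em).to_numpy()
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d_out = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(d_in, d_out, atol=1e-8)

    def test_duplicated_sample_identical_coordinates(self, rng):
        v = rng.normal(size=(10, 4))
        v[:, 3] = v[:, 0]
        coords = integrate.classical_mds(make_matrix(v)).to_numpy()
        assert np.allclose(coords[0], coords[3], atol=1e-8)

    def test_batch_structure_visible_then_removed(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.metrics import silhouette_score
        cfg = SimulationConfig(n_batches=3, samples_per_batch=30, n_genes=500,
                               gamma_sd=2.0, seed=7)
        em, _, _ = synthdata.simulate_integration_study(cfg)
        pre = silhouette_score(integrate.classical_mds(em), em.batch)
        adj, _ = integrate.combat_adjust(em)
        post = silhouette_score(integrate.classical_mds(adj), adj.batch)
        assert pre > 0.3
        assert post < 0.1


# sva::ComBat (R, parametric, 2 batches of 5) output for CB_FIXTURE, frozen
# as an independent oracle of the empirical-Bayes adjustment.
CB_FIXTURE = np.array([
    [7.304717, 5.960016, 7.750451, 7.940565, 5.048965, 6.89782, 8.32784, 7.883757, 8.183199, 7.346956],
    [7.879398, 7.777792, 7.066031, 8.127241, 7.467509, 7.340708, 8.568751, 7.241117, 9.07845, 8.150074],
    [6.815138, 6.31907, 8.222541, 6.845471, 6.571672, 7.847866, 8.732309, 8.565444, 8.612733, 8.630821],
    [9.141648, 6.593585, 6.487757, 6.186227, 7.615979, 9.328972, 8.086053, 7.359844, 7.375519, 8.850593],
    [7.743254, 7.543154, 6.33449, 7.232161, 7.116686, 8.418689, 9.071429, 8.423596, 8.878914, 8.267579],
    [7.289119, 7.631288, 5.542844, 6.680329, 6.529627, 7.561122, 7.924858, 9.694941, 7.334169, 9.168278],
])
CB_SVA_EXPECTED = np.array([
    [7.81042092978, 6.72599303091, 8.16988105145, 8.32319760700, 5.99128016784,
     6.18042745901, 7.82295713418, 7.31288069767, 7.65682160129, 6.69630780207],
    [8.19005142486, 8.09803119526, 7.45341955180, 8.41451228118, 7.81702108854,
     7.09098468857, 8.18274134454, 7.00244614626, 8.63587472488, 7.81052848111],
    [7.49467705162, 7.09543046076, 8.62738637716, 7.51908972657, 7.29873018448,
     7.09856872804, 8.10938846134, 7.91868037184, 7.97272642610, 7.99339899328],
    [9.46250270268, 7.34716829252, 7.25931269007, 7.00899047091, 8.19593271041,
     8.75328549359, 7.43558447254, 6.66568205670, 6.68230016576, 8.24612412849],
    [8.21872101454, 8.05612087537, 7.07396727914, 7.80340970556, 7.70957536738,
     7.82018446475, 8.52105229956, 7.82545326774, 8.31434278089, 7.65793282012],
    [8.01354498997, 8.31477301133, 6.47621413011, 7.47759752799, 7.34492722392,
     6.80909953037, 7.15461041242, 8.83600279214, 6.59351808885, 8.33572842372],
])


class TestCombat:
    def test_matches_reference_empirical_bayes_implementation(self):
        """Parametric adjustment reproduces the R sva::ComBat output frozen
        above (same location/scale EB model) to ~1e-4."""
        em = make_matrix(CB_FIXTURE, batch=["A"] * 5 + ["B"] * 5)
        adj, model = integrate.combat_adjust(em, mode="parametric")
        assert np.allclose(adj.values, CB_SVA_EXPECTED, atol=1e-4)
        assert (model.delta_star > 0).all()

    def test_single_batch_is_identity(self, rng):
        em = make_matrix(rng.normal(7, 1, (20, 8)), batch=["A"] * 8)
        with pytest.warns(UserWarning, match="single batch"):
            adj, _ = integrate.combat_adjust(em)
        assert np.allclose(adj.values, em.values, atol=1e-8)

    def test_planted_additive_shifts_removed(self, rng):
        """Per-gene additive shifts of SD 2 between two batches: after
        adjustment the per-gene batch mean differences are centered on zero
        with their spread shrunk at least 5-fold."""
        vals = rng.normal(7, 1, (400, 40))
        vals[:, 20:] += rng.normal(0.0, 2.0, (400, 1))
        em = make_matrix(vals, batch=["A"] * 20 + ["B"] * 20)
        pre_diff = em.values[:, 20:].mean(axis=1) - em.values[:, :20].mean(axis=1)
        adj, _ = integrate.combat_adjust(em)
        post_diff = adj.values[:, 20:].mean(axis=1) - adj.values[:, :20].mean(axis=1)
        assert abs(post_diff.mean()) < 0.05
        assert post_diff.std() < pre_diff.std() / 5

    def test_batch_prediction_accuracy_drops(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.model_selection import cross_val_score
        from sklearn.neighbors import NearestCentroid
        cfg = SimulationConfig(n_batches=4, samples_per_batch=30, n_genes=600,
                               gamma_sd=2.0, seed=21)
        em, _, _ = synthdata.simulate_integration_study(cfg)
        pre = cross_val_score(NearestCentroid(), em.values.T, em.batch, cv=5).mean()
        adj, _ = integrate.combat_adjust(em)
        post = cross_val_score(NearestCentroid(), adj.values.T, adj.batch, cv=5).mean()
        assert pre > 0.9
        assert post <= 0.6

    def test_biological_covariate_preserved(self, rng):
        """A planted 2-group effect declared as covariate survives adjustment
        within 20% of its planted size."""
        G, n = 500, 60
        vals = rng.normal(7, 1, (G, n))
        batch = ["A"] * 30 + ["B"] * 30
        group = np.r_[np.tile([0, 1], 15), np.tile([1, 0], 15)].astype(float)
        planted = 1.5
        vals[:50, group == 1] += planted
        vals[:, 30:] += rng.normal(2.0, 1.0, (G, 1))
        em = make_matrix(vals, batch=batch)
        adj, _ = integrate.combat_adjust(em, covariates=group)
        diff = (adj.values[:50][:, group == 1].mean()
                - adj.values[:50][:, group == 0].mean())
        assert abs(diff - planted) < 0.2 * planted

    def test_near_idempotent(self, rng):
        """Re-adjusting adjusted data is a small perturbation: the second
        pass changes values by well under a tenth of the first correction
        (exact idempotence is impossible for any empirical-Bayes shrinkage,
        which deliberately leaves a residual between raw and shrunken batch
        effects; the reference implementation behaves the same way)."""
        vals = rng.normal(7, 1, (200, 30))
        vals[:, 15:] += rng.normal(0.0, 2.0, (200, 1))
        em = make_matrix(vals, batch=["A"] * 15 + ["B"] * 15)
        adj1, _ = integrate.combat_adjust(em)
        adj2, _ = integrate.combat_adjust(adj1)
        first = np.sqrt(np.mean((adj1.values - em.values) ** 2))
        second = np.sqrt(np.mean((adj2.values - adj1.values) ** 2))
        assert second < first / 10

    def test_nonparametric_mode_close_to_parametric(self, rng):
        vals = rng.normal(7, 1, (150, 24))
        vals[:, 12:] += 1.5
        em = make_matrix(vals, batch=["A"] * 12 + ["B"] * 12)
        par, _ = integrate.combat_adjust(em, mode="parametric")
        non, _ = integrate.combat_adjust(em, mode="nonparametric", seed=0)
        # same location/scale model, different shrinkage: values track closely
        assert np.corrcoef(par.values.ravel(), non.values.ravel())[0, 1] > 0.99

    def test_singleton_batch_rejected(self, rng):
        em = make_matrix(rng.normal(size=(10, 5)), batch=["A"] * 4 + ["B"])
        with pytest.raises(ValueError, match="single sample"):
            integrate.combat_adjust(em)

    def test_confounded_covariate_rejected(self, rng):
        em = make_matrix(rng.normal(size=(10, 6)), batch=["A"] * 3 + ["B"] * 3)
        confounded = np.array([1.0, 1, 1, 0, 0, 0])  # identical to batch
        with pytest.raises(ValueError, match="confounded"):
            integrate.combat_adjust(em, covariates=confounded)


class TestTwoClusterQC:
    def test_recovers_separated_blobs_exactly(self, rng):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score
        G, n = 100, 30
        profile_a = rng.normal(0, 1, G)
        profile_b = rng.normal(0, 1, G)
        vals = np.empty((G, n))
        vals[:, :15] = profile_a[:, None] + rng.normal(0, 0.5, (G, 15))
        vals[:, 15:] = profile_b[:, None] + rng.normal(0, 0.5, (G, 15))
        em = make_matrix(vals)
        clinical = make_clinical(rng.exponential(30, n), np.ones(n, int),
                                 sample_ids=em.sample_ids)
        labels, _ = integrate.two_cluster_survival_qc(em, clinical)
        truth = np.r_[np.zeros(15), np.ones(15)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_null_survival_p_calibrated(self):
        """Cluster labels carry no survival information: p < 0.05 in ~5% of
        simulations."""
        rejections = 0
        n_sims = 60
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            G, n = 60, 40
            vals = rng.normal(0, 1, (G, n))
            vals[:, n // 2:] += rng.normal(0, 1.5, (G, 1))  # 2 real clusters
            em = make_matrix(vals)
            clinical = make_clinical(rng.exponential(30, n),
                                     (rng.random(n) < 0.8).astype(int),
                                     sample_ids=em.sample_ids)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, res = integrate.two_cluster_survival_qc(em, clinical)
            if res is not None and res.p_value < 0.05:
                rejections += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], n_sims, 0.05)
        assert lo <= rejections <= hi

    def test_identical_survival_records_zero_statistic(self, rng):
        G, n = 50, 20
        vals = rng.normal(0, 1, (G, n))
        vals[:, 10:] += rng.normal(0, 2, (G, 1))
        em = make_matrix(vals)
        os_months = np.tile(np.arange(1.0, 11.0), 2)
        clinical = make_clinical(os_months, np.ones(n, int), sample_ids=em.sample_ids)
        labels, res = integrate.two_cluster_survival_qc(em, clinical)
        if res is not None and len(set(labels[:10])) == 1:
            assert res.statistic == pytest.approx(0.0, abs=1e-9)
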