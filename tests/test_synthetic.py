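"""Synthetic landscapes, genetic distances, genotypes, gravity networks."""

import json

import numpy as np
import pytest

import landgen as lg
from landgen.synthetic import (SyntheticTruth, make_landscape,
                               sample_locations, simulate_genetic_distances,
                               simulate_genotypes, simulate_gravity_network)


class TestMakeLandscape:
    @pytest.mark.parametrize("kind", ["smooth", "dem", "categorical"])
    def test_same_seed_bit_identical(self, kind):
        a = make_landscape(kind, (20, 20), seed=3)
        b = make_landscape(kind, (20, 20), seed=3)
        assert np.array_equal(a.values, b.values)

    def test_smoothing_increases_autocorrelation_range(self):
        def lag1_corr(vals):
            return np.corrcoef(vals[:, :-1].ravel(), vals[:, 1:].ravel())[0, 1]

        rough = make_landscape("smooth", (40, 40), seed=3, smoothing=1.0)
        smooth = make_landscape("smooth", (40, 40), seed=3, smoothing=5.0)
        assert lag1_corr(smooth.values) > lag1_corr(rough.values)

    def test_categorical_classes_partition_cells(self):
        cat = make_landscape("categorical", (20, 20), seed=3, n_classes=3)
        assert set(np.unique(cat.values)) == {1.0, 2.0, 3.0}

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_landscape("smooth", (10, 10))


class TestSimulateGeneticDistances:
    def test_zero_variances_affine_in_commute(self, smooth_raster):
        truth = SyntheticTruth(lg.TransformSpec("Monomolecular", 3.0, 100.0),
                               sigma2_u=0.0, sigma2_e=0.0, seed=1)
        locs = sample_locations(smooth_raster, 8, seed=2)
        y = simulate_genetic_distances(truth, smooth_raster, locs)
        from landgen.resistance import build_graph, commute_distance_nodes
        from landgen.surfaces import apply_transform, rescale

        g = build_graph(apply_transform(rescale(smooth_raster), truth.true_spec))
        cm = commute_distance_nodes(g, g.snap_nodes(locs))
        iu = np.triu_indices(8, k=1)
        c = cm[iu]
        z = (c - c.mean()) / c.std()
        assert np.allclose(y.values[iu], truth.beta0 + truth.beta1 * z)

    def test_mlpe_refit_recovers_slope(self, smooth_raster, recovery_truth):
        """Closing the loop: the MLPE estimator recovers the planted slope
        from the generator's own output."""
        locs = sample_locations(smooth_raster, 20, seed=5)
        betas = []
        for rep in range(30):
            truth = SyntheticTruth(recovery_truth.true_spec,
                                   sigma2_u=recovery_truth.sigma2_u,
                                   sigma2_e=recovery_truth.sigma2_e,
                                   seed=6000 + rep)
            y = simulate_genetic_distances(truth, smooth_raster, locs)
            from landgen.resistance import build_graph, commute_distance_nodes
            from landgen.surfaces import apply_transform, rescale

            g = build_graph(apply_transform(rescale(smooth_raster),
                                            truth.true_spec))
            cm = commute_distance_nodes(g, g.snap_nodes(locs))
            np.fill_diagonal(cm, np.nan)
            fit = lg.fit_mlpe(y, lg.PairwiseMatrix(y.ids, cm, "commute"))
            betas.append(fit.beta[1])
        se = np.std(betas) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 1.0) < 3 * max(se, 1e-4)

    def test_truth_serializes(self, recovery_truth):
        d = json.loads(recovery_truth.to_json())
        assert d["true_spec"]["family"] == "Monomolecular"


class TestSimulateGenotypes:
    def test_no_decay_removes_between_site_structure(self, smooth_raster,
                                                     recovery_truth):
        locs = sample_locations(smooth_raster, 6, seed=4)
        t = simulate_genotypes(recovery_truth, smooth_raster, locs,
                               n_per_site=6, decay=0.0, n_loci=12)
        d = lg.dps(t).values
        same = [d[i, j] for i in range(t.n) for j in range(i + 1, t.n)
                if t.localities[i] == t.localities[j]]
        diff = [d[i, j] for i in range(t.n) for j in range(i + 1, t.n)
                if t.localities[i] != t.localities[j]]
        assert abs(np.mean(same) - np.mean(diff)) < 0.05

    def test_strong_decay_creates_isolation_by_resistance(self, smooth_raster,
                                                          recovery_truth):
        locs = sample_locations(smooth_raster, 8, seed=4)
        t = simulate_genotypes(recovery_truth, smooth_raster, locs,
                               n_per_site=5, decay=3.0, freq_sd=1.5)
        ar = lg.rousset_ar(t)
        eu = lg.euclidean_matrix(t.ids, t.xy)
        out = lg.ibd_regression(ar, eu)
        assert out["pearson_r"] > 0.1

    def test_planted_clones_recovered_and_filtered(self, smooth_raster,
                                                   recovery_truth):
        locs = sample_locations(smooth_raster, 5, seed=4)
        t = simulate_genotypes(recovery_truth, smooth_raster, locs,
                               n_per_site=6, n_loci=15, n_clone_pairs=2)
        clone_ids = [i for i in t.ids if i.startswith("clone")]
        rel = lg.estimate_relatedness(t)
        for cid in clone_ids:
            row = rel.values[t.ids.index(cid)]
            assert np.nanmax(row) >= 0.99
        kept = lg.filter_related(t, rel, 0.5)
        sub = rel.subset(kept.ids).values
        assert not np.any(np.nan_to_num(sub) > 0.5)

    def test_same_seed_reproducible(self, smooth_raster, recovery_truth):
        locs = sample_locations(smooth_raster, 5, seed=4)
        a = simulate_genotypes(recovery_truth, smooth_raster, locs)
        b = simulate_genotypes(recovery_truth, smooth_raster, locs)
        assert np.array_equal(a.alleles, b.alleles)


class TestSimulateGravityNetwork:
    def test_same_seed_identical(self):
        a, _ = simulate_gravity_network(n_sites=6, per_site=3, seed=2)
        b, _ = simulate_gravity_network(n_sites=6, per_site=3, seed=2)
        assert a.edges.equals(b.edges)

    def test_negative_distance_effect_recovered_consistently(self):
        hits = 0
        for rep in range(20):
            net, _ = simulate_gravity_network(
                n_sites=8, per_site=3, beta={"distance": -0.03},
                seed=7000 + rep)
            fit = lg.fit_gravity(net, covariates=())
            hits += fit.params.loc["log_distance", "beta"] < 0
        assert hits >= 19
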