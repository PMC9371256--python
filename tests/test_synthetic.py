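"""Generator tests: planted structure must be present and recoverable."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from crossmodalfc.connectivity import aec, plv
from crossmodalfc.datatypes import CANONICAL_BANDS
from crossmodalfc.mapping import fit_all_regions, fit_regional_model
from crossmodalfc.synthetic import (
    SyntheticConfig,
    make_band_fc_set,
    make_band_timeseries,
    make_context_maps,
    make_crossmodal_truth,
    make_geometry,
    make_subject_ensemble,
)

BETA = CANONICAL_BANDS[3]


class TestGeometry:
    def test_unit_norm_and_mirror_symmetry(self):
        geo = make_geometry(10, seed=4)
        norms = np.linalg.norm(geo.coords, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-12
        left = geo.coords[geo.indices("L")]
        right = geo.coords[geo.indices("R")]
        mirrored = left * np.array([-1.0, 1.0, 1.0])
        # each left point has its exact mirror on the right
        assert np.abs(np.sort(mirrored, axis=0) - np.sort(right, axis=0)).max() < 1e-15

    def test_seeded_determinism(self):
        a = make_geometry(50, seed=9)
        b = make_geometry(50, seed=9)
        assert (a.coords == b.coords).all()
        c = make_geometry(50, seed=10)
        assert not (a.coords == c.coords).all()

    @pytest.mark.parametrize("n", [9, 8, 13])
    def test_invalid_parcel_counts_rejected(self, n):
        with pytest.raises(ValueError):
            make_geometry(n, seed=0)


class TestBandFCSet:
    def test_symmetry_bounds_and_diagonal(self, bands200):
        for _, m in bands200:
            assert (m.values == m.values.T).all()
            assert (np.abs(m.values) <= 1.0).all()
            assert (np.diag(m.values) == 0).all()

    def test_distance_decay_near_vs_far(self, geometry200, config200):
        bands = make_band_fc_set(geometry200, config200)
        d = geometry200.distance_matrix()
        iu = np.triu_indices(geometry200.n, k=1)
        dist = d[iu]
        lo, hi = np.quantile(dist, [0.1, 0.9])
        for _, m in bands:
            vals = m.values[iu]
            assert vals[dist <= lo].mean() > vals[dist >= hi].mean()

    def test_infinite_decay_is_distance_flat(self):
        """With decay_length >> sphere size and no modulation the expected
        connectivity is distance-flat: exactly so without edge noise, and
        within 2 standard errors of zero in a Monte-Carlo over seeds."""
        iu = np.triu_indices(20, k=1)
        cfg0 = SyntheticConfig(
            n_parcels=20, seed=0, decay_length=1e9, mod_amplitude=0.0,
            edge_noise_sd=0.0,
        )
        geo0 = make_geometry(20, seed=0)
        m0 = make_band_fc_set(geo0, cfg0)[0].values
        d0 = geo0.distance_matrix()[iu]
        med0 = np.median(d0)
        assert abs(m0[iu][d0 <= med0].mean() - m0[iu][d0 > med0].mean()) < 1e-8

        diffs = []
        for seed in range(1000):
            cfg = SyntheticConfig(
                n_parcels=20, seed=seed, decay_length=1e9, mod_amplitude=0.0
            )
            geo = make_geometry(20, seed=seed)
            m = make_band_fc_set(geo, cfg)[0].values
            d = geo.distance_matrix()[iu]
            med = np.median(d)
            diffs.append(m[iu][d <= med].mean() - m[iu][d > med].mean())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 2 * se

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_parcels=20, decay_length=0.0)


class TestCrossmodalTruth:
    def test_noiseless_constant_weights_identifiable(self):
        cfg = SyntheticConfig(n_parcels=60, seed=2)
        geo = make_geometry(60, seed=2)
        bands = make_band_fc_set(geo, cfg)
        w = np.tile(np.array([0.2, 0.1, 0.15, 0.3, 0.05, 0.1]), (60, 1))
        haemo, truth = make_crossmodal_truth(
            bands, geo, cfg, weights=w, noise_sd=np.zeros(60)
        )
        assert truth.target_r2.max() <= 1.0 + 1e-12
        for i in (0, 17, 59):
            res = fit_regional_model(haemo, bands, i)
            assert np.abs(res.coefficients[1:] - w[i]).max() < 1e-8
            assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_graded_noise_targets_anticorrelate_with_hierarchy(self, crossmodal200):
        _, truth = crossmodal200
        rs = spearmanr(truth.target_r2, truth.hierarchy).statistic
        assert rs <= -0.9

    def test_zero_weights_give_null_model_fit(self, geometry200, config200, bands200):
        """With no planted signal the mean fitted adjusted R^2 is ~0."""
        w = np.zeros((200, 6))
        means = []
        for seed in range(50):
            cfg = SyntheticConfig(n_parcels=200, seed=seed)
            haemo, _ = make_crossmodal_truth(
                bands200, geometry200, cfg, weights=w, noise_sd=np.full(200, 0.2)
            )
            _, r2_map = fit_all_regions(haemo, bands200)
            means.append(r2_map.mean())
        assert abs(np.mean(means)) < 0.05

    def test_dimension_mismatch_rejected(self, bands200):
        geo = make_geometry(100, seed=0)
        with pytest.raises(ValueError):
            make_crossmodal_truth(bands200, geo, SyntheticConfig(n_parcels=200))


class TestSubjectEnsemble:
    def test_zero_noise_reproduces_group(self, crossmodal200, bands200):
        haemo, _ = crossmodal200
        subs, sub_bands = make_subject_ensemble(haemo, bands200, 3, 0.0, seed=5)
        for s in subs:
            assert (s.values == haemo.values).all()
        for bs in sub_bands:
            for (_, g), (_, s) in zip(bands200, bs):
                assert (g.values == s.values).all()

    def test_mean_converges_to_group(self):
        cfg = SyntheticConfig(n_parcels=20, seed=3)
        geo = make_geometry(20, seed=3)
        bands = make_band_fc_set(geo, cfg)
        haemo, _ = make_crossmodal_truth(bands, geo, cfg)
        sd = 0.1
        subs, _ = make_subject_ensemble(haemo, bands, 500, sd, seed=8)
        mean = np.mean([s.values for s in subs], axis=0)
        assert np.abs(mean - haemo.values).max() < 5 * sd / np.sqrt(500)

    def test_seeded_determinism(self, crossmodal200, bands200):
        haemo, _ = crossmodal200
        a, _ = make_subject_ensemble(haemo, bands200, 3, 0.05, seed=5)
        b, _ = make_subject_ensemble(haemo, bands200, 3, 0.05, seed=5)
        for x, y in zip(a, b):
            assert (x.values == y.values).all()

    def test_too_few_subjects_rejected(self, crossmodal200, bands200):
        haemo, _ = crossmodal200
        with pytest.raises(ValueError):
            make_subject_ensemble(haemo, bands200, 1, 0.05, seed=5)


class TestContextMaps:
    def test_identical_donors_have_unit_stability(self, geometry200, config200):
        from crossmodalfc.context import differential_stability

        anchor = geometry200.coords[:, 2]
        _, panel, _ = make_context_maps(
            geometry200, anchor, config200, donor_consistency=1.0, n_genes=5
        )
        for gene in panel.genes:
            assert differential_stability(panel, gene) == pytest.approx(1.0, abs=1e-12)

    def test_depth_peak_is_planted(self, geometry200, config200):
        anchor = geometry200.coords[:, 2]
        depths, _, _ = make_context_maps(
            geometry200, anchor, config200, peak_depth=31
        )
        corr = np.array(
            [
                abs(spearmanr(depths.values[:, d], anchor).statistic)
                for d in range(depths.n_depths)
            ]
        )
        assert int(np.argmax(corr)) == 31

    def test_structural_matrix_sparse_and_nonnegative(self, geometry200, config200):
        anchor = geometry200.coords[:, 2]
        _, _, sc = make_context_maps(geometry200, anchor, config200)
        off = ~np.eye(sc.n, dtype=bool)
        assert (sc.values >= 0).all()
        assert (sc.values[off] == 0).any()

    def test_nonfinite_anchor_rejected(self, geometry200, config200):
        anchor = np.full(geometry200.n, np.nan)
        with pytest.raises(ValueError):
            make_context_maps(geometry200, anchor, config200)


class TestBandTimeseries:
    def test_locked_pair_has_unit_plv(self):
        ts = make_band_timeseries(
            4, 120.0, 250.0, band=BETA, locking_pairs=[(0, 1)], seed=3
        )
        p = plv(ts, BETA)
        assert p.values[0, 1] >= 0.99

    def test_envelope_pair_survives_leakage_correction(self):
        """Mean corrected AEC of a planted common-envelope pair over seeds."""
        vals = []
        for seed in range(20):
            ts = make_band_timeseries(
                2, 300.0, 250.0, band=BETA, envelope_pairs=[(0, 1)], seed=seed
            )
            vals.append(aec(ts, BETA, leakage_correction=True).values[0, 1])
        assert np.mean(vals) >= 0.7

    def test_unplanted_pair_has_null_plv(self):
        ts = make_band_timeseries(3, 300.0, 250.0, band=BETA, seed=4)
        p = plv(ts, BETA)
        assert abs(p.values[0, 1]) < 0.1

    def test_aliasing_rejected(self):
        higamma = CANONICAL_BANDS[5]
        with pytest.raises(ValueError):
            make_band_timeseries(2, 10.0, 180.0, band=higamma, seed=0)
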