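import numpy as np
import pytest
from scipy import ndimage

from sandicortex.phantom import (CohortConfig, GeometryConfig, REGION_PRESETS,
                                 _draw_region_params, generate_cohort,
                                 make_geometry, sample_lesions, simulate_dwi)
from sandicortex.signal import ball_signal


class TestGeometry:
    def test_partial_volumes_partition_unity_inside_brain(self):
        geom = make_geometry()
        pv = geom.partial_volumes()
        total = pv["csf"] + pv["gm"] + pv["wm"] + pv["lesion"]
        inside = total > 0
        # within the head, tissue fractions plus background sum to one by
        # construction of the block aggregation
        assert total.max() <= 1.0 + 1e-6
        assert (total[inside] <= 1 + 1e-6).all()

    def test_ribbon_thickness_along_radial_lines(self):
        cfg = GeometryConfig()
        geom = make_geometry(config=cfg)
        # count GM voxels along the three axes through the center
        c = cfg.n // 2
        for line in (geom.labels[c, c, :], geom.labels[c, :, c],
                     geom.labels[:, c, c]):
            runs = np.where(line == 2)[0]
            half = runs[runs > c]
            thickness = half.size * cfg.voxel_mm
            assert abs(thickness - (cfg.r_gm - cfg.r_wm)) <= 1.0
            assert 2.0 <= thickness <= 4.5

    def test_interior_voxel_is_pure_gm(self):
        geom = make_geometry()
        pv = geom.partial_volumes()
        assert pv["gm"].max() == pytest.approx(1.0)


class TestLesionSampler:
    def test_count_distribution_median(self):
        rng = np.random.default_rng(5)
        cfg = CohortConfig()
        counts = [max(1, int(round(rng.lognormal(
            np.log(cfg.lesion_count_median), cfg.lesion_count_log_sd))))
            for _ in range(10_000)]
        assert abs(np.median(counts) - 8) <= 1

    def test_single_small_lesion_is_one_cluster(self):
        geom = make_geometry()
        cfg = CohortConfig(lesion_count_log_sd=1e-9, lesion_count_median=1.0,
                           lesion_radius_log_sd=1e-9,
                           lesion_radius_median_mm=1.0)
        labels, records = sample_lesions(geom, cfg, np.random.default_rng(3))
        assert len(records) == 1
        lab, n_comp = ndimage.label(labels == 4)
        assert n_comp == 1

    def test_lesions_touch_gm_wm_interface(self):
        geom = make_geometry()
        cfg = CohortConfig()
        labels, records = sample_lesions(geom, cfg, np.random.default_rng(9))
        lesion = labels == 4
        # every lesion component must contain former WM and former GM voxels
        assert (geom.labels[lesion] == 2).any() or (geom.labels[lesion] == 3).any()
        lab, n_comp = ndimage.label(lesion)
        for comp in range(1, n_comp + 1):
            orig = geom.labels[lab == comp]
            assert set(np.unique(orig)) <= {2, 3}


class TestTruthDraws:
    def test_degenerate_sd_returns_renormalized_means(self):
        rng = np.random.default_rng(0)
        out = _draw_region_params(REGION_PRESETS["table3_ms"], rng, sd_scale=0.0)
        preset = REGION_PRESETS["table3_ms"]["lesion"]
        total = preset["f_is"][0] + preset["f_in"][0] + preset["f_ec"][0]
        assert out["lesion"].f_is == pytest.approx(preset["f_is"][0] / total)
        assert out["lesion"].r_s == pytest.approx(preset["r_s"][0])

    def test_law_of_large_numbers_on_lesion_f_is(self):
        rng = np.random.default_rng(1)
        draws = np.array([_draw_region_params(
            REGION_PRESETS["table3_ms"], rng)["lesion"].f_is
            for _ in range(4000)])
        preset = REGION_PRESETS["table3_ms"]["lesion"]
        total = preset["f_is"][0] + preset["f_in"][0] + preset["f_ec"][0]
        se = preset["f_is"][1] / np.sqrt(draws.size)
        assert abs(draws.mean() - preset["f_is"][0] / total) < 4 * se + 5e-3

    def test_fractions_always_valid(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = _draw_region_params(REGION_PRESETS["table3_ms"], rng)["lesion"]
            fr = np.array([p.f_is, p.f_in, p.f_ec])
            assert np.all(fr > 0) and np.all(fr < 1)
            assert fr.sum() == pytest.approx(1.0, abs=1e-9)


class TestRicianNoise:
    def test_rayleigh_mean_at_zero_signal(self):
        rng = np.random.default_rng(7)
        sigma = 1.0
        draws = np.sqrt(rng.normal(0, sigma, 10_000) ** 2
                        + rng.normal(0, sigma, 10_000) ** 2)
        assert draws.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2),
                                             abs=0.02)

    def test_infinite_snr_equals_noiseless(self, scheme):
        cfg = CohortConfig(n_ms=1, n_hc=1, master_seed=4)
        subjects, _ = generate_cohort(cfg)
        s = subjects[0]
        rng = np.random.default_rng(0)
        noiseless = simulate_dwi(s, scheme, cfg, rng, noiseless=True).copy()
        high_snr_cfg = CohortConfig(n_ms=1, n_hc=1, master_seed=4, snr=1e9)
        noisy = simulate_dwi(s, scheme, high_snr_cfg, np.random.default_rng(0))
        np.testing.assert_allclose(noisy, noiseless, atol=1e-5)

    def test_pure_csf_voxel_attenuates_like_free_water(self, scheme):
        cfg = CohortConfig(n_ms=1, n_hc=1, master_seed=4)
        subjects, _ = generate_cohort(cfg)
        s = subjects[1]                      # HC: no lesions
        dwi = simulate_dwi(s, scheme, cfg, np.random.default_rng(0),
                           noiseless=True)
        pure_csf = (s.pv["csf"] >= 1.0)
        assert pure_csf.any()
        i, j, k = np.argwhere(pure_csf)[0]
        b6_vols = np.isclose(scheme.b, 6.0)
        expected = ball_signal(6.0, 3.0)     # exp(-18) ~ 0
        np.testing.assert_allclose(dwi[i, j, k, b6_vols], expected, atol=1e-7)

    def test_snr_guard(self):
        with pytest.raises(ValueError):
            CohortConfig(snr=0.0)


class TestCohort:
    def test_default_sizes(self):
        cfg = CohortConfig()
        assert cfg.n_ms == 41 and cfg.n_hc == 34

    def test_small_cohort_structure(self):
        cfg = CohortConfig(n_ms=2, n_hc=2, master_seed=11)
        subjects, manifest = generate_cohort(cfg)
        assert len(subjects) == 4
        assert sum(s.group == "MS" for s in subjects) == 2
        for s in subjects:
            if s.group == "HC":
                assert s.n_lesions == 0
                assert not s.masks.lesion.any()
            else:
                assert s.n_lesions >= 1
                assert s.masks.lesion.any() or s.pv["lesion"].max() <= 0.25
        assert len(manifest["subjects"]) == 4

    def test_same_seed_is_bit_identical(self):
        cfg = CohortConfig(n_ms=2, n_hc=1, master_seed=13)
        s1, m1 = generate_cohort(cfg)
        s2, m2 = generate_cohort(cfg)
        assert m1 == m2
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.labels, b.labels)
            np.testing.assert_array_equal(a.truth["gm_f_is"],
                                          b.truth["gm_f_is"])
            assert a.age == b.age and a.sex == b.sex and a.seed == b.seed

    def test_region_params_regions_match_group(self):
        cfg = CohortConfig(n_ms=1, n_hc=1, master_seed=3)
        subjects, _ = generate_cohort(cfg)
        ms = subjects[0]
        hc = subjects[1]
        assert set(ms.region_params) == {"na_cortex", "outer_layer",
                                         "inner_layer", "lesion"}
        assert set(hc.region_params) == {"cortex"}

    def test_invalid_group_size(self):
        with pytest.raises(ValueError):
            CohortConfig(n_ms=0)
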