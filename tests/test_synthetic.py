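"""Synthetic study generator: design frequencies, field coherence,
response model and determinism."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mossmap import (StudyConfig, ZoneSpec, CovariateSpec, StudyGenerator,
                     default_study_config, generate_sites, simulate_response,
                     generate_grid, cll_transform)


class TestGenerateSites:
    def test_species_counts_near_design_frequencies(self):
        cfg = default_study_config(seed=3)
        sites = generate_sites(cfg)
        assert sites.n == 445
        counts = sites.data["moss_species"].value_counts()
        for sp, expected in zip(("Hc", "Pp", "Tt", "Ps", "Hs"),
                                (227, 186, 27, 4, 1)):
            p = expected / 445
            sigma = np.sqrt(445 * p * (1 - p))
            assert abs(counts.get(sp, 0) - expected) <= 3 * sigma + 1e-9

    def test_zone_allocation_matches_weights(self):
        cfg = default_study_config(seed=3)
        sites = generate_sites(cfg)
        zc = sites.data["zone"].value_counts().to_dict()
        assert zc == {"Atlantic": 220, "Continental": 147,
                      "Mediterranean": 49, "Alpine": 29}

    def test_no_zeros_without_zero_inflation(self, small_config):
        cfg = small_config
        specs = [CovariateSpec(s.name, s.kind, s.buffer_radii_km,
                               s.corr_length_m, s.rank_corr_target,
                               0.0, s.scale, s.log_sd)
                 for s in cfg.covariates]
        cfg2 = StudyConfig(10, cfg.zones, cfg.species_probs, cfg.tree_probs,
                           specs, cfg.true_alpha, cfg.true_betas, cfg.sigma,
                           cfg.cd_max, seed=4)
        with pytest.warns(UserWarning):  # 10 sites, 9 covariates
            sites = generate_sites(cfg2)
        vals = sites.data[sites.covariates].to_numpy()
        assert not np.any(vals == 0.0)
        assert sites.meta["overfit_warning"]

    def test_fixed_seed_reproducible(self, small_config):
        a = generate_sites(small_config).data
        b = generate_sites(small_config).data
        assert a.to_csv() == b.to_csv()

    def test_land_use_percent_bounds(self, small_sites):
        for col in small_sites.covariates:
            if col.startswith(("Forest", "Sea")):
                v = small_sites.data[col]
                assert (v >= 0).all() and (v <= 100).all()

    def test_buffer_family_rank_correlation_exceeds_target(self, small_config):
        hits = 0
        reps = 20
        for s in range(reps):
            cfg = default_study_config(seed=100 + s, n_sites=200)
            sites = generate_sites(cfg)
            fam = [f"Forest_{r}" for r in (1, 5, 10, 15)]
            rho = spearmanr(sites.data[fam]).statistic
            target = next(c.rank_corr_target for c in cfg.covariates
                          if c.name == "Forest")
            off_diag = rho[~np.eye(4, dtype=bool)]
            if off_diag.min() > target:
                hits += 1
        assert hits >= int(0.95 * reps)

    def test_zero_inflation_proportion(self, small_config):
        # Sea family configured with 60% zeros; spatial correlation makes
        # any single realisation's proportion noisy, so check the
        # marginal probability averaged over independent field draws
        cfg = small_config
        covs = [CovariateSpec("Sea", "percent", (5, 10), corr_length_m=8e3,
                              zero_inflation=0.6)]
        props = []
        for s in range(20):
            cfg_s = StudyConfig(200, cfg.zones, cfg.species_probs,
                                cfg.tree_probs, covs, cfg.true_alpha, {},
                                cfg.sigma, cfg.cd_max, seed=300 + s)
            sites = generate_sites(cfg_s)
            props.append(np.mean(sites.data["Sea_5"] == 0.0))
        assert np.mean(props) == pytest.approx(0.6, abs=0.08)
        # zeros are spatially coherent: realised proportions vary by seed
        assert max(props) > 0.4


class TestSimulateResponse:
    def test_identity_case_of_inverse_link(self, small_config):
        cfg = StudyConfig(small_config.n_sites, small_config.zones,
                          small_config.species_probs, small_config.tree_probs,
                          small_config.covariates, true_alpha=0.0,
                          true_betas={}, sigma=0.0, cd_max=1.5, seed=2)
        gen = StudyGenerator(cfg)
        sites = gen.simulate_response(gen.generate_sites())
        assert np.allclose(sites.data["cd"], 1.5 / np.e, atol=1e-12)

    def test_noiseless_round_trip_recovers_eta(self, small_config):
        cfg = StudyConfig(small_config.n_sites, small_config.zones,
                          small_config.species_probs, small_config.tree_probs,
                          small_config.covariates, small_config.true_alpha,
                          small_config.true_betas, sigma=0.0,
                          cd_max=1.5, seed=2)
        gen = StudyGenerator(cfg)
        sites = gen.simulate_response(gen.generate_sites())
        eta = gen.linear_predictor(sites.data)
        z = cll_transform(sites.data["cd"].to_numpy(), 1.5)
        assert np.allclose(z, eta, atol=1e-10)

    def test_noise_scale_matches_sigma(self, small_config):
        cfg = StudyConfig(10_000, small_config.zones,
                          small_config.species_probs, small_config.tree_probs,
                          small_config.covariates, small_config.true_alpha,
                          small_config.true_betas, sigma=0.3,
                          cd_max=1.5, seed=9)
        gen = StudyGenerator(cfg)
        sites = gen.simulate_response(gen.generate_sites())
        eta = gen.linear_predictor(sites.data)
        z = cll_transform(sites.data["cd"].to_numpy(), 1.5)
        assert np.std(z - eta) == pytest.approx(0.3, rel=0.02)

    def test_responses_strictly_inside_bounds(self, small_config):
        cfg = StudyConfig(100_000, small_config.zones,
                          small_config.species_probs, small_config.tree_probs,
                          small_config.covariates, small_config.true_alpha,
                          small_config.true_betas, sigma=0.8,
                          cd_max=1.5, seed=13)
        gen = StudyGenerator(cfg)
        y = gen.simulate_response(gen.generate_sites()).data["cd"].to_numpy()
        assert np.all(y > 0.0) and np.all(y < 1.5)

    def test_missing_covariate_in_betas_raises(self, small_sites, small_config):
        cfg = small_config
        bad = StudyConfig(cfg.n_sites, cfg.zones, cfg.species_probs,
                          cfg.tree_probs, cfg.covariates, 0.0,
                          {"NotAColumn": 1.0}, 0.1, seed=1)
        with pytest.raises(KeyError, match="NotAColumn"):
            simulate_response(small_sites, bad)


class TestGenerateGrid:
    def test_cell_count_arithmetic(self):
        cfg = StudyConfig(
            10, [ZoneSpec("Z", 0.0, 100e3, 0.0, 80e3)],
            {"Hc": 1.0}, {"deciduous": 1.0},
            [CovariateSpec("EMEP_air", "positive", ())],
            0.0, {}, 0.1, seed=1)
        grid = generate_grid(cfg, 2_000.0)
        assert len(grid) == 50 * 40

    def test_site_and_coincident_cell_share_field_values(self, small_config):
        gen = StudyGenerator(small_config)
        sites = gen.generate_sites()
        row = sites.data.iloc[3]
        at_site = gen.covariate_values(np.array([row["x"]]),
                                       np.array([row["y"]]))
        for col in sites.covariates:
            assert at_site[col].iloc[0] == pytest.approx(row[col], abs=1e-9)

    def test_fixed_seed_identical_grid(self, small_config):
        g1 = generate_grid(small_config, 10_000.0)
        g2 = generate_grid(small_config, 10_000.0)
        pd.testing.assert_frame_equal(g1, g2)

    def test_empty_extent_errors(self, small_config):
        cfg = StudyConfig(10, [ZoneSpec("Z", 0.0, 0.0, 0.0, 0.0)],
                          {"Hc": 1.0}, {"deciduous": 1.0},
                          small_config.covariates, 0.0, {}, 0.1, seed=1)
        with pytest.raises(ValueError, match="empty"):
            generate_grid(cfg, 2_000.0)


class TestConfigValidation:
    def test_probability_vectors_must_sum_to_one(self, small_config):
        with pytest.raises(ValueError, match="sum to 1"):
            StudyConfig(10, small_config.zones, {"Hc": 0.6, "Pp": 0.5},
                        small_config.tree_probs, small_config.covariates,
                        0.0, {}, 0.1)

    def test_overlapping_zones_rejected(self, small_config):
        with pytest.raises(ValueError, match="overlap"):
            StudyConfig(10, [ZoneSpec("A", 0, 10, 0, 10),
                             ZoneSpec("B", 5, 15, 0, 10)],
                        small_config.species_probs, small_config.tree_probs,
                        small_config.covariates, 0.0, {}, 0.1)
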