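"""The synthetic campaign generator: determinism, design counts, recovery."""

import numpy as np
import pandas as pd
import pytest

import canopygp as cg
from canopygp.simulate import _crown_bump


class TestGenotypeSimulation:
    def test_shape_domain_and_determinism(self, small_config):
        gm = cg.simulate_genotypes(small_config)
        assert (gm.n_accessions, gm.n_markers) == (36, 300)
        assert np.isin(gm.dosages, (0.0, 1.0, 2.0)).all()
        again = cg.simulate_genotypes(small_config)
        np.testing.assert_array_equal(gm.dosages, again.dosages)
        assert gm.accession_ids == again.accession_ids

    def test_empirical_frequencies_track_generating_frequencies(self):
        # unstructured panel so the generating frequency is the ancestral one
        cfg = cg.SimulationConfig(
            seed=5, n_accessions=500, n_genotyped=500, n_markers=400, fst=0.0
        )
        gm = cg.simulate_genotypes(cfg)
        observed = gm.allele_frequencies()
        # replay the generator's stream: the subset draw precedes the freqs
        rng = cfg.rng("genotypes")
        rng.choice(cfg.n_accessions, size=cfg.n_genotyped, replace=False)
        generating = rng.uniform(0.05, 0.5, size=400)
        assert np.abs(observed - generating).max() < 0.05
        assert np.abs(observed - generating).mean() < 0.02

    def test_structured_panel_has_inflated_relatedness(self):
        flat = cg.SimulationConfig(seed=2, n_accessions=120, n_genotyped=120,
                                   n_markers=400, fst=0.0)
        structured = cg.SimulationConfig(seed=2, n_accessions=120, n_genotyped=120,
                                         n_markers=400, fst=0.3)
        off = lambda cfg: cg.genomic_relationship_matrix(
            cg.simulate_genotypes(cfg)
        ).matrix[np.triu_indices(120, 1)].std()
        assert off(structured) > 2 * off(flat)


class TestPhenotypeSimulation:
    def test_realized_plot_heritability_near_target(self):
        estimates = []
        for seed in range(5):
            cfg = cg.SimulationConfig(seed=seed, n_accessions=172, n_genotyped=151,
                                      n_markers=400, h2=0.5)
            layout = cg.build_layout(cfg)
            g, plants = cg.simulate_phenotypes(cg.simulate_genotypes(cfg), layout, cfg)
            plot_means = plants.groupby("plot_id")["height_m"].mean()
            df = layout.to_frame().set_index("plot_id")
            df["y"] = plot_means
            df["g"] = df["accession_id"].map(g)
            sub = df[df["treatment"] == "normal"]
            h2_hat = sub["g"].var() / sub["y"].var()
            estimates.append(h2_hat)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.1)

    def test_low_fertilization_shrinks_mean_height(self):
        cfg = cg.SimulationConfig(seed=3, n_accessions=100, n_genotyped=100, n_markers=200,
                                  low_fertilization_factor=0.8)
        layout = cg.build_layout(cfg)
        _, plants = cg.simulate_phenotypes(cg.simulate_genotypes(cfg), layout, cfg)
        df = plants.merge(layout.to_frame()[["plot_id", "treatment"]], on="plot_id")
        means = df.groupby("treatment")["height_m"].mean()
        expected_drop = cfg.mean_height_m * (1 - cfg.low_fertilization_factor)
        assert means["normal"] - means["low"] == pytest.approx(expected_drop, abs=0.1)

    def test_zero_genetic_sd_removes_accession_differences(self):
        cfg = cg.SimulationConfig(seed=4, n_accessions=50, n_genotyped=50, n_markers=100,
                                  genetic_sd_m=0.0)
        layout = cg.build_layout(cfg)
        g, _ = cg.simulate_phenotypes(cg.simulate_genotypes(cfg), layout, cfg)
        assert np.allclose(g, 0.0)

    def test_heights_truncated_at_floor(self, small_experiment):
        assert (small_experiment.truth.plants["height_m"] >= 0.2).all()


class TestLayout:
    def test_default_design_counts(self):
        layout = cg.build_layout(cg.SimulationConfig())
        assert len(layout) == 688
        counts = layout.to_frame().groupby("accession_id").size()
        assert (counts == 4).all()
        combos = layout.to_frame().groupby(["treatment", "replication"]).size()
        assert (combos == 172).all()

    def test_grid_cells_unique_and_rectangles_disjoint(self, small_experiment):
        df = small_experiment.layout.to_frame()
        cells = list(zip(df["grid_row"], df["grid_col"]))
        assert len(set(cells)) == len(cells)
        # rectangles implied by distinct grid cells never overlap
        assert df.duplicated(subset=["x_m", "y_m"]).sum() == 0

    def test_layout_csv_round_trip(self, tmp_path, small_experiment):
        path = tmp_path / "layout.csv"
        small_experiment.layout.write_csv(path)
        back = cg.FieldLayout.read_csv(path)
        pd.testing.assert_frame_equal(back.to_frame(), small_experiment.layout.to_frame())


class TestRuler:
    def test_default_campaign_measures_1376_plants(self):
        cfg = cg.SimulationConfig(seed=1, n_markers=50, n_qtl=10)
        layout = cg.build_layout(cfg)
        _, plants = cg.simulate_phenotypes(cg.simulate_genotypes(cfg), layout, cfg)
        table, measurements = cg.simulate_ruler(plants, cfg)
        assert len(table) == 688
        assert len(measurements) == 688 * 2 == 1376

    def test_noiseless_census_recovers_true_plot_mean(self):
        cfg = cg.SimulationConfig(
            seed=9, n_accessions=20, n_genotyped=20, n_markers=50, n_qtl=10,
            ruler_noise_sd_m=0.0, plants_sampled_for_ruler=5,
        )
        layout = cg.build_layout(cfg)
        _, plants = cg.simulate_phenotypes(cg.simulate_genotypes(cfg), layout, cfg)
        table, _ = cg.simulate_ruler(plants, cfg)
        truth = plants.groupby("plot_id")["height_m"].mean()
        merged = table.set_index("plot_id")["height_m"]
        np.testing.assert_allclose(merged[truth.index], truth, atol=1e-12)

    def test_deterministic_under_fixed_seed(self, small_config, small_experiment):
        again = cg.simulate_experiment(small_config)
        pd.testing.assert_frame_equal(again.ruler, small_experiment.ruler)
        np.testing.assert_array_equal(again.canopy.values, small_experiment.canopy.values)

    def test_oversampling_raises(self):
        with pytest.raises(ValueError):
            cg.SimulationConfig(plants_sampled_for_ruler=6, plants_per_plot=5)


class TestSceneRendering:
    def test_dense_canopy_99th_percentile_recovers_block_truth(self):
        """Full cover, no spill: the 99th percentile recovers the analytic
        central-block canopy maximum.

        Tolerance: most block pixels sit on crown plateaus at the true
        height, each carrying differenced DSM noise of sd sigma*sqrt(2)
        (two independent flights), so the block's 99th percentile is an
        upper order statistic with expected offset ~ z_0.99 * sigma*sqrt(2)
        ~ 2.3 sigma above truth.  The mean error must stay within 3 sigma
        and the per-plot values must track the truth almost perfectly.
        """
        cfg = cg.SimulationConfig(
            seed=21, n_accessions=30, n_genotyped=30, n_markers=100,
            resolution_m=0.05, canopy_cover=1.0, spill_coefficient=0.0,
        )
        exp = cg.simulate_experiment(cfg)
        table = cg.extract_plot_heights(exp.canopy, exp.ground, exp.layout, [99])
        merged = table.merge(exp.truth.plots, on="plot_id")
        err = merged["height_m"] - merged["block_max_m"]
        assert 0 < err.mean() < 3 * cfg.dsm_noise_sd_m  # small positive noise offset
        assert err.abs().mean() < 3 * cfg.dsm_noise_sd_m
        assert cg.pearson_r(merged["height_m"], merged["block_max_m"]) > 0.98

    def test_no_spill_no_overestimation_trend(self):
        """spill = 0: r2 must not rise with neighbour height ratio r1."""
        slopes = []
        for seed in range(5):
            cfg = cg.SimulationConfig(
                seed=seed, n_accessions=40, n_genotyped=40, n_markers=100,
                resolution_m=0.05, spill_coefficient=0.0,
            )
            exp = cg.simulate_experiment(cfg)
            uav = cg.extract_plot_heights(exp.canopy, exp.ground, exp.layout, [50])
            tab = pd.concat([uav, exp.ruler], ignore_index=True)
            adj = cg.adjacency_ratios(exp.layout, tab).dropna()
            slopes.append(np.polyfit(adj["r1"], adj["r2"], 1)[0])
        assert abs(np.mean(slopes)) < 0.05

    def test_spill_contaminates_plots_with_tall_neighbours(self):
        cfg = cg.SimulationConfig(
            seed=2, n_accessions=40, n_genotyped=40, n_markers=100, resolution_m=0.05
        )
        exp = cg.simulate_experiment(cfg)
        uav = cg.extract_plot_heights(exp.canopy, exp.ground, exp.layout, [50])
        tab = pd.concat([uav, exp.ruler], ignore_index=True)
        adj = cg.adjacency_ratios(exp.layout, tab).dropna()
        flagged = adj[adj["r1"] >= 1.5]["r2"]
        assert flagged.mean() > adj["r2"].mean()

    def test_lower_camera_noise_gives_higher_agreement(self):
        wins = 0
        for seed in range(10):
            rs = {}
            for profile, sd in cg.CAMERA_PROFILES.items():
                cfg = cg.SimulationConfig(
                    seed=seed, n_accessions=30, n_genotyped=30, n_markers=100,
                    resolution_m=0.05, dsm_noise_sd_m=sd,
                )
                exp = cg.simulate_experiment(cfg)
                uav = cg.extract_plot_heights(exp.canopy, exp.ground, exp.layout, [50])
                tab = pd.concat([uav, exp.ruler], ignore_index=True)
                sel = cg.select_replicates(tab, exp.layout, "lower")
                rs[profile] = cg.pearson_r(sel["ph_uav"], sel["ph_r"])
            wins += rs["nirgb"] >= rs["rgb"]
        assert wins > 5

    def test_crown_bump_profile(self):
        dist = np.array([0.0, 0.3, 0.6, 0.8, 1.2])
        bump = _crown_bump(2.0, 1.0, dist)
        assert bump[0] == 2.0  # apex
        assert bump[1] == 2.0  # inside plateau (0.6 r)
        np.testing.assert_allclose(bump[2], 2.0, atol=1e-9)  # plateau edge
        assert 0 < bump[3] < 2.0  # decaying flank
        assert bump[4] == 0.0  # outside footprint
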