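"""Synthetic-population generator: Mendelian expectations, trait control,
layout invariants, reflectance calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import phenogs as pg
from phenogs.simulate import checks_per_block


def expected_residual_heterozygosity(selfing_generations: int) -> float:
    """Single-locus Markov-chain oracle for repeated selfing.

    States (AA, Aa, aa) with selfing transition [[1, .25, 0],
    [0, .5, 0], [0, .25, 1]]; starting from Aa, the heterozygous mass
    after g generations is 0.5**g.  Multiplied by the probability a locus
    is heterozygous in the F1 of (common x founder) parents whose alleles
    are i.i.d. Bernoulli(p) with p ~ U(0.1, 0.9).
    """
    T = np.array([[1.0, 0.25, 0.0], [0.0, 0.5, 0.0], [0.0, 0.25, 1.0]])
    state = np.linalg.matrix_power(T, selfing_generations) @ np.array([0, 1, 0])
    p_het_f1 = quad(lambda p: 2 * p * (1 - p), 0.1, 0.9)[0] / 0.8
    return p_het_f1 * state[1]


class TestGenotypes:
    def test_residual_heterozygosity_matches_selfing_markov_chain(self):
        cfg = pg.SimulationConfig(
            n_families=10, lines_per_family=30, n_markers=1000,
            n_chromosomes=5, selfing_generations=5, seed=2,
        )
        m = pg.simulate_nam_genotypes(cfg)
        het = float((m.geno.to_numpy() == 1).mean())
        expected = expected_residual_heterozygosity(5)
        assert het == pytest.approx(expected, rel=0.2)

    def test_heterozygosity_halves_per_extra_selfing_generation(self):
        hets = {}
        for g in (2, 4):
            cfg = pg.SimulationConfig(
                n_families=10, lines_per_family=30, n_markers=1000,
                n_chromosomes=5, selfing_generations=g, seed=3,
            )
            m = pg.simulate_nam_genotypes(cfg)
            hets[g] = (m.geno.to_numpy() == 1).mean()
        assert hets[2] / hets[4] == pytest.approx(4.0, rel=0.25)

    def test_same_seed_gives_identical_matrices(self):
        cfg = pg.SimulationConfig(
            n_families=3, lines_per_family=10, n_markers=200,
            n_chromosomes=2, seed=9, marker_missing_rate=0.05,
        )
        a = pg.simulate_nam_genotypes(cfg)
        b = pg.simulate_nam_genotypes(cfg)
        pd.testing.assert_frame_equal(a.geno, b.geno)

    def test_codes_are_valid_and_family_labels_attached(self, small_markers):
        vals = small_markers.geno.to_numpy()
        assert set(np.unique(vals[np.isfinite(vals)])) <= {0.0, 1.0, 2.0}
        assert small_markers.families.nunique() == 6
        # minor-allele orientation
        assert (small_markers.maf() <= 0.5 + 1e-12).all()

    def test_rare_allele_injection_creates_low_maf_markers(self):
        cfg = pg.SimulationConfig(
            n_families=6, lines_per_family=20, n_markers=400,
            n_chromosomes=4, low_maf_fraction=0.2, seed=4,
        )
        m = pg.simulate_nam_genotypes(cfg)
        assert (m.maf() < 0.1).mean() > 0.1

    def test_marker_count_must_divide_across_chromosomes(self):
        with pytest.raises(ValueError, match="divide"):
            pg.SimulationConfig(n_markers=101, n_chromosomes=10)


class TestConfigValidation:
    def test_non_psd_genetic_corr_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            pg.SimulationConfig(
                trait_names=("a", "b", "c"),
                target_h2={"a": 0.5, "b": 0.5, "c": 0.5},
                genetic_corr=bad,
            )

    def test_h2_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pg.SimulationConfig(
                trait_names=("a",), target_h2={"a": 1.2},
                genetic_corr=np.eye(1),
            )

    def test_check_fraction_bounds(self):
        with pytest.raises(ValueError, match="check_fraction"):
            pg.SimulationConfig(check_fraction=1.0)


class TestTraits:
    def test_h2_one_means_phenotype_equals_breeding_value(self):
        cfg = pg.SimulationConfig(
            n_families=4, lines_per_family=15, n_markers=200, n_chromosomes=2,
            n_environments=2, trait_names=("t",), target_h2={"t": 1.0},
            genetic_corr=np.eye(1), residual_corr=np.eye(1), seed=5,
        )
        m = pg.simulate_nam_genotypes(cfg)
        table, truth = pg.simulate_traits(m, cfg)
        for env in cfg.environments:
            vals = table[table.environment == env].set_index("genotype_id")["value"]
            np.testing.assert_allclose(
                vals.loc[m.line_ids].to_numpy(),
                truth.true_breeding_values["t"].to_numpy(),
            )

    def test_breeding_values_equal_markers_times_effects(self, small_study,
                                                         small_markers):
        truth = small_study[4]
        X = small_markers.geno.to_numpy()
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        W = X - X.mean(axis=0)
        np.testing.assert_allclose(
            W @ truth.true_marker_effects.to_numpy(),
            truth.true_breeding_values.to_numpy(), atol=1e-10,
        )

    def test_genetic_correlation_of_breeding_values_is_controlled(self):
        cfg = pg.SimulationConfig(
            n_families=50, lines_per_family=20, n_markers=1000,
            n_chromosomes=10, n_environments=1, trait_names=("A", "B"),
            target_h2={"A": 0.5, "B": 0.5},
            genetic_corr=np.array([[1.0, 0.7], [0.7, 1.0]]), seed=6,
        )
        m = pg.simulate_nam_genotypes(cfg)
        _, truth = pg.simulate_traits(m, cfg)
        r = truth.realized_genetic_corr.loc["A", "B"]
        assert r == pytest.approx(0.7, abs=0.05)

    def test_zero_genetic_correlation_stays_near_zero(self):
        """Null r_G: unlinked effects give breeding-value correlations
        centered on zero.  Linkage and family structure shrink the
        effective marker dimension, so single draws scatter with sd
        near 0.09; the mean over seeds must sit tight around zero."""
        rs = []
        for seed in (7, 17, 27, 37, 47):
            cfg = pg.SimulationConfig(
                n_families=50, lines_per_family=20, n_markers=1000,
                n_chromosomes=10, n_environments=1, trait_names=("A", "B"),
                target_h2={"A": 0.5, "B": 0.5}, genetic_corr=np.eye(2),
                seed=seed,
            )
            m = pg.simulate_nam_genotypes(cfg)
            _, truth = pg.simulate_traits(m, cfg)
            rs.append(truth.realized_genetic_corr.loc["A", "B"])
        assert abs(np.mean(rs)) < 0.08
        assert np.max(np.abs(rs)) < 0.3

    def test_realized_h2_tracks_target(self, small_study, small_config):
        truth = small_study[4]
        for tr in small_config.trait_names:
            assert truth.realized_h2[tr] == pytest.approx(
                small_config.target_h2[tr], abs=0.08
            )


class TestFieldLayout:
    def test_checks_per_block_rounding_rule(self):
        assert checks_per_block(0.15, 20) == 3
        assert checks_per_block(0.05, 20) == 2   # floor of two for replication

    def test_unreplicated_entries_appear_exactly_once(self, small_study):
        plots = small_study[2]
        for _, env_df in plots.groupby("environment"):
            entries = env_df[~env_df.is_check]
            assert entries.genotype_id.value_counts().max() == 1
            checks = env_df[env_df.is_check]
            per_block = checks.groupby("block_id").genotype_id.nunique()
            assert (per_block == checks.genotype_id.nunique()).all()

    def test_zero_noise_layout_reproduces_genotype_values(self):
        cfg = pg.SimulationConfig(
            n_families=3, lines_per_family=10, n_markers=200, n_chromosomes=2,
            n_environments=1, block_effect_sd=0.0, plot_error_sd=0.0, seed=8,
        )
        m = pg.simulate_nam_genotypes(cfg)
        table, _ = pg.simulate_traits(m, cfg)
        plots = pg.simulate_field_layout(table, cfg)
        entries = plots[~plots.is_check]
        ref = table.pivot_table(index="genotype_id", columns="trait",
                                values="value")
        for tr in cfg.trait_names:
            got = entries.set_index("genotype_id")[tr]
            np.testing.assert_allclose(
                got.to_numpy(), ref.loc[got.index, tr].to_numpy(), atol=1e-12
            )


class TestReflectance:
    def test_recomputed_indices_track_latent_targets(self):
        cfg = pg.SimulationConfig(
            n_families=25, lines_per_family=20, n_markers=500,
            n_chromosomes=5, n_environments=1, seed=12,
        )
        rng = np.random.default_rng(1)
        latent = pd.DataFrame({
            "plot_id": [f"P{i}" for i in range(500)],
            "environment": "E1",
            "NDVI": rng.normal(0, 1, 500),
            "NWI": rng.normal(0, 1, 500),
            "PRI": rng.normal(0, 1, 500),
        })
        panel = pg.simulate_reflectance(latent, cfg)
        sri = pg.compute_indices(panel)
        merged = sri.merge(latent, on=["plot_id", "environment"],
                           suffixes=("_c", "_t"))
        for ix in ("NDVI", "NWI", "PRI"):
            r = np.corrcoef(merged[f"{ix}_c"], merged[f"{ix}_t"])[0, 1]
            assert r > 0.9, f"{ix} calibration correlation {r:.3f}"

    def test_constant_targets_give_constant_spectra(self):
        cfg = pg.SimulationConfig(reflectance_noise_sd=0.0, seed=13)
        latent = pd.DataFrame({
            "plot_id": [f"P{i}" for i in range(20)],
            "environment": "E1", "stage": "heading",
            "NDVI": 0.5, "NWI": -0.1, "PRI": 0.02,
        })
        panel = pg.simulate_reflectance(latent, cfg)
        sri = pg.compute_indices(panel)
        bands = [c for c in panel.columns if c.startswith("R")]
        assert panel[bands].std().max() == pytest.approx(0.0, abs=1e-12)
        assert sri[["NDVI", "NWI", "PRI"]].std().max() == pytest.approx(
            0.0, abs=1e-12
        )

    def test_reflectance_bounded_in_unit_interval(self, small_study):
        refl = small_study[3]
        bands = [c for c in refl.columns if c.startswith("R")]
        vals = refl[bands].to_numpy()
        assert vals.min() > 0.0 and vals.max() < 1.0

    def test_missing_required_band_errors(self):
        cfg = pg.SimulationConfig(
            # everything present except 970 nm, required by NWI and WI
            band_wavelengths=(430, 531, 550, 570, 680, 700, 780, 800,
                              880, 900),
        )
        latent = pd.DataFrame({
            "plot_id": ["P1"], "environment": "E1", "NDVI": [0.5],
        })
        with pytest.raises(ValueError, match="970.*NWI"):
            pg.simulate_reflectance(latent, cfg)
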