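"""Generator correctness: map functions, meiosis, bulk genotyping, trial
design, yield adjustment, GxE and trait-redundancy structure."""

import numpy as np
import pandas as pd
import pytest

from phenosel.simdata import (
    ConfigurationError,
    CrossPlan,
    GeneticMap,
    SimConfig,
    TraitPanelConfig,
    TruthConfig,
    adjust_yield,
    build_design,
    bulk_genotype,
    haldane_recomb,
    make_cross,
    scaled_replication_spec,
    simulate_founders,
    simulate_study,
    simulate_traits,
    simulate_yield,
    full_trial_replication_spec,
)
from phenosel.trait_reduction import unique_trait_count


class TestHaldane:
    def test_closed_form(self):
        assert haldane_recomb(0) == 0.0
        assert haldane_recomb(1e9) == pytest.approx(0.5)
        # (1 - exp(-2 * 0.5)) / 2 at 50 cM
        assert haldane_recomb(50) == pytest.approx(0.5 * (1 - np.exp(-1.0)), abs=1e-6)
        assert haldane_recomb(50) == pytest.approx(0.3161, abs=5e-5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_recomb(-1.0)


class TestFounders:
    def test_default_pool_size_and_homozygosity(self):
        gmap = GeneticMap.uniform(60, n_chrom=3)
        founders = simulate_founders(27, gmap, seed=1)
        assert founders.shape == (27, 60)
        assert set(np.unique(founders.values())) <= {0.0, 2.0}

    def test_symmetric_frequency_mean_dosage(self):
        gmap = GeneticMap.uniform(40, n_chrom=2)
        founders = simulate_founders(400, gmap, maf_low=0.5, maf_high=0.5, seed=2)
        means = founders.values().mean(axis=0)
        assert np.abs(means - 1.0).max() < 0.25  # binomial MC error at n=400
        assert means.mean() == pytest.approx(1.0, abs=0.02)

    def test_determinism(self):
        gmap = GeneticMap.uniform(30, n_chrom=2)
        a = simulate_founders(10, gmap, seed=7)
        b = simulate_founders(10, gmap, seed=7)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)

    def test_invalid_maf_bounds(self):
        gmap = GeneticMap.uniform(10, n_chrom=1)
        with pytest.raises(ConfigurationError):
            simulate_founders(5, gmap, maf_low=0.4, maf_high=0.2, seed=0)


class TestCrossing:
    @pytest.fixture()
    def gmap(self):
        return GeneticMap.uniform(100, n_chrom=5, chrom_length_cM=100.0)

    def test_identical_parents_no_segregation(self, gmap, rng):
        parent = 2.0 * (rng.random(gmap.n_markers) < 0.5)
        out = make_cross(np.stack([parent, parent]), 5, gmap, rng)
        assert np.allclose(out, parent)

    def test_heterozygous_founder_rejected(self, gmap, rng):
        p = np.ones((2, gmap.n_markers))  # dosage 1 = heterozygous
        with pytest.raises(ValueError):
            make_cross(p, 2, gmap, rng)

    def test_mendelian_segregation_mean(self, gmap, rng):
        """At a marker where parents carry 0 and 2, mean pooled offspring
        dosage over many lines approaches 1 (Mendelian conservation)."""
        p1 = np.zeros(gmap.n_markers)
        p2 = np.full(gmap.n_markers, 2.0)
        out = make_cross(np.stack([p1, p2]), 400, gmap, rng, n_plants=6)
        means = out.mean(axis=0)
        # SE of a line's pooled dosage is < sqrt(2*0.5*0.5)/... ~ 0.5; at
        # n=400 lines, 3 SE ~ 0.075 per marker
        assert np.abs(means - 1.0).max() < 0.15
        # linkage correlates markers within a line, so the grand mean has
        # SE ~ sd(line genome mean)/sqrt(n_lines) ~ 0.013; allow ~3 SE
        assert means.mean() == pytest.approx(1.0, abs=0.04)

    def test_f4_residual_heterozygosity(self, gmap, rng):
        """Single-plant heterozygosity at F4 is 1/8 per segregating locus
        (halved by each selfing from 1/2 at F2)."""
        p1 = np.zeros(gmap.n_markers)
        p2 = np.full(gmap.n_markers, 2.0)
        out = make_cross(np.stack([p1, p2]), 300, gmap, rng, n_plants=1)
        het = np.mean(out == 1.0)
        assert het == pytest.approx(0.125, abs=0.01)

    def test_three_way_cross_mean(self, gmap, rng):
        """(A x B) F1 x C: with A,B carrying 0 and C carrying 2, expected
        offspring dosage is 1 (half the genome from C)."""
        p = np.stack([np.zeros(gmap.n_markers), np.zeros(gmap.n_markers),
                      np.full(gmap.n_markers, 2.0)])
        out = make_cross(p, 400, gmap, rng)
        assert out.mean() == pytest.approx(1.0, abs=0.03)


class TestBulkGenotype:
    def test_constant_pool(self):
        assert bulk_genotype(np.full((6, 3), 2.0)).tolist() == [2.0, 2.0, 2.0]

    def test_arithmetic_mean(self):
        pool = np.array([[0.0], [2.0], [2.0], [2.0], [0.0], [2.0]])
        assert bulk_genotype(pool)[0] == pytest.approx(4.0 / 3.0)

    def test_large_pool_expectation_under_selfing_series(self, rng):
        """F4 genotype frequencies within a segregating family are
        (3/8, 2/8, 3/8) for dosages (0, 1, 2); the pooled mean tends to 1."""
        draws = rng.choice([0.0, 1.0, 2.0], size=(200000, 1), p=[3 / 8, 2 / 8, 3 / 8])
        assert bulk_genotype(draws)[0] == pytest.approx(1.0, abs=0.01)

    def test_empty_pool_rejected(self):
        with pytest.raises(ConfigurationError):
            bulk_genotype(np.empty((0, 3)))


class TestDesign:
    def test_full_trial_replication_totals(self, rng):
        """Every line gets exactly 4 plots across the four environments and
        each environment's plot count equals the line total (2,992)."""
        spec = full_trial_replication_spec()
        env_ids = [c for c in spec.columns if c != "n_lines"]
        lines = [f"L{i:04d}" for i in range(int(spec["n_lines"].sum()))]
        design = build_design(lines, env_ids, spec, rng)
        per_line = design.groupby("line").size()
        assert (per_line == 4).all()
        per_env = design.groupby("env").size()
        assert (per_env == len(lines)).all()
        assert len(lines) == 2992

    def test_subblocks_nest_in_blocks(self, rng):
        spec = scaled_replication_spec(100, ["E1", "E2", "E3", "E4"])
        lines = [f"L{i}" for i in range(100)]
        design = build_design(lines, ["E1", "E2", "E3", "E4"], spec, rng)
        blocks_per_sub = design.groupby(["env", "sub_block"])["block"].nunique()
        assert (blocks_per_sub == 1).all()

    def test_degenerate_single_environment(self, rng):
        spec = pd.DataFrame({"n_lines": [6], "OnlyEnv": [1]})
        design = build_design([f"L{i}" for i in range(6)], ["OnlyEnv"], spec, rng)
        assert len(design) == 6
        assert design["line"].is_unique

    def test_mismatched_spec_rejected(self, rng):
        spec = pd.DataFrame({"n_lines": [5], "E1": [1]})
        with pytest.raises(ConfigurationError):
            build_design([f"L{i}" for i in range(6)], ["E1"], spec, rng)


class TestAdjustYield:
    def test_reference_and_extremes(self):
        assert adjust_yield(8.5, 15.0) == pytest.approx(8.5)
        assert adjust_yield(8.5, 100.0) == 0.0
        assert adjust_yield(10.0, 20.0) == pytest.approx(10 * 80 / 85)
        assert adjust_yield(10.0, 20.0) == pytest.approx(9.4118, abs=1e-4)

    def test_moisture_domain(self):
        with pytest.raises(ValueError):
            adjust_yield(5.0, 101.0)


class TestSimulateYield:
    def _setup(self, n_lines, envs, seed=3):
        gmap = GeneticMap.uniform(80, n_chrom=4)
        founders = simulate_founders(10, gmap, seed=seed)
        plan = CrossPlan.random(founders.line_ids, max(n_lines // 25, 2), 0, 25,
                                np.random.default_rng(seed))
        from phenosel.simdata import default_environments, simulate_population

        geno = simulate_population(plan, founders, np.random.default_rng(seed + 1))
        env = default_environments()[:envs] if isinstance(envs, int) else envs
        spec = scaled_replication_spec(len(geno.line_ids), [e.id for e in env])
        design = build_design(geno.line_ids, [e.id for e in env], spec,
                              np.random.default_rng(seed + 2))
        return geno, env, design

    def test_perfect_correlation_identical_rankings(self, rng):
        geno, env, design = self._setup(50, 2)
        truth = TruthConfig(env_corr=1.0, sigma_block=0.0, sigma_subblock=0.0,
                            sigma_resid=1e-12, sigma_meas=1e-12)
        plots, st = simulate_yield(geno, env, design, truth, rng)
        g = st.genetic_values
        rho = np.corrcoef(g.iloc[:, 0], g.iloc[:, 1])[0, 1]
        assert rho == pytest.approx(1.0, abs=1e-8)

    def test_configured_correlation_recovered(self, rng):
        geno, env, design = self._setup(1000, 2, seed=9)
        truth = TruthConfig(env_corr=0.3, h2=0.4)
        plots, st = simulate_yield(geno, env, design, truth, rng)
        g = st.genetic_values.to_numpy()
        rho = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert rho == pytest.approx(0.3, abs=0.05)

    def test_zero_genetic_variance_uncorrelated_line_means(self, rng):
        geno, env, design = self._setup(200, 2, seed=5)
        truth = TruthConfig(h2=0.0, env_corr=0.3)
        plots, st = simulate_yield(geno, env, design, truth, rng)
        means = plots.groupby(["line", "env"])["yield_t_ha"].mean().unstack()
        rho = np.corrcoef(means.iloc[:, 0], means.iloc[:, 1])[0, 1]
        assert abs(rho) < 0.2

    def test_heritability_recovery(self, rng):
        """R^2 of plot yield on true genetic value tracks the configured
        plot-level h^2 (block effects are a small, finite-draw nuisance)."""
        geno, env, design = self._setup(1000, 2, seed=13)
        truth = TruthConfig(h2=0.4, env_corr=0.5, sigma_block=0.0)
        plots, st = simulate_yield(geno, env, design, truth, rng)
        r2 = []
        for e in plots["env"].unique():
            sub = plots[plots["env"] == e]
            r2.append(np.corrcoef(sub["yield_t_ha"], sub["genetic_value"])[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(0.4, abs=0.05)

    def test_non_psd_matrix_rejected(self, rng):
        geno, env, design = self._setup(50, 2)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ConfigurationError):
            simulate_yield(geno, env, design, TruthConfig(env_corr=bad), rng)


class TestSimulateTraits:
    def test_redundancy_groups_collapse_to_group_count(self, tiny_sim):
        panel = tiny_sim.panel
        traits = tiny_sim.plots[panel["trait_id"]]
        n_groups = panel["group"].nunique()
        assert unique_trait_count(traits, 0.9) == n_groups

    def test_soil_traits_uninformative(self, tiny_sim):
        panel = tiny_sim.panel
        soil = panel.loc[panel["category"] == "soil", "trait_id"]
        y = tiny_sim.plots["yield_t_ha"]
        for t in soil:
            assert abs(np.corrcoef(tiny_sim.plots[t], y)[0, 1]) < 0.25

    def test_pure_signal_trait_tracks_yield(self, rng):
        """With full signal share and loading, every trait is a deterministic
        affine map of the (measurement-error-free) yield deviation."""
        sim = simulate_study(SimConfig.tiny(), seed=3)
        cfg = TraitPanelConfig(
            categories=(
                __import__("phenosel.simdata", fromlist=["CategorySpec"]).CategorySpec(
                    "hyperspectral", 2, 2, ("F3",), 1.0
                ),
            ),
            within_loading=1.0,
        )
        traits, panel = simulate_traits(sim.plots, cfg, rng)
        target = sim.plots["yield_t_ha"] - sim.plots["meas_error"]
        for env in sim.plots["env"].unique():
            sel = sim.plots["env"] == env
            for t in panel["trait_id"]:
                r = np.corrcoef(traits.loc[sel, t], target[sel])[0, 1]
                assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_negative_noise_sd_rejected(self, tiny_sim, rng):
        cfg = TraitPanelConfig.tiny()
        cfg.trait_noise_sd = -1.0
        with pytest.raises(ConfigurationError):
            simulate_traits(tiny_sim.plots, cfg, rng)


class TestDeterminism:
    def test_whole_study_bit_identical(self):
        a = simulate_study(SimConfig.tiny(), seed=42)
        b = simulate_study(SimConfig.tiny(), seed=42)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.plots, b.plots)
        pd.testing.assert_frame_equal(a.truth.genetic_values,
                                      b.truth.genetic_values)

    def test_seed_changes_output(self):
        a = simulate_study(SimConfig.tiny(), seed=42)
        b = simulate_study(SimConfig.tiny(), seed=43)
        assert not a.plots["yield_t_ha"].equals(b.plots["yield_t_ha"])
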