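"""Generator behavior: gradients, Gaussian responses, interaction kernels."""

import numpy as np
import pandas as pd
import pytest

from nicheweb.synthetic_community import (
    SimulationConfig,
    SiteRecord,
    TrueTaxonParams,
    edge_length_inputs,
    expected_abundances,
    generate_abundances,
    generate_interactions,
    generate_sites,
    generate_study,
    generate_taxa,
    interaction_rates,
    stream_rng,
    write_community,
)


def make_taxon(taxon_id="t1", level="plant", optimum=(10.0, 90.0), breadth=(3.0, 60.0), baseline=5.0):
    return TrueTaxonParams(
        taxon_id=taxon_id,
        trophic_level=level,
        env_optimum=optimum,
        env_breadth=breadth,
        trait_means=(3.0, 2.0, 1.0),
        trait_sd=(0.3, 0.2, 0.2),
        baseline_abundance=baseline,
    )


class TestSites:
    def test_zero_noise_gives_even_temperature_spacing(self):
        config = SimulationConfig(n_sites=8, temperature_range=(5, 15), temperature_noise_sd=0.0, seed=1)
        temps = [s.mean_temperature for s in generate_sites(config)]
        assert np.allclose(temps, np.linspace(5, 15, 8))

    def test_same_seed_reproduces_site_table(self):
        config = SimulationConfig(seed=42)
        a, b = generate_sites(config), generate_sites(config)
        assert a == b

    def test_aspects_fall_on_folded_axis(self):
        config = SimulationConfig(n_sites=30, seed=7)
        assert all(0 <= s.aspect <= 180 for s in generate_sites(config))

    def test_single_site_is_invalid(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_sites=1)

    def test_site_record_rejects_bad_aspect(self):
        with pytest.raises(ValueError, match="aspect"):
            SiteRecord("s1", "local", 10.0, 190.0)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"coupling_theta": -1.0},
            {"matching_gamma": -0.1},
            {"total_interactions": 0},
            {"n_plants": 0},
            {"temperature_range": (15, 5)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestAbundances:
    def test_site_at_optimum_has_maximal_expected_abundance(self):
        config = SimulationConfig(n_sites=9, temperature_noise_sd=0.0, seed=0)
        sites = generate_sites(config)
        taxon = make_taxon(optimum=(sites[4].mean_temperature, sites[4].aspect))
        means = expected_abundances([taxon], sites)
        assert means.loc["t1"].idxmax() == sites[4].site_id

    def test_infinite_breadth_limit_is_flat(self):
        config = SimulationConfig(n_sites=6, seed=0)
        sites = generate_sites(config)
        taxon = make_taxon(breadth=(1e9, 1e9))
        means = expected_abundances([taxon], sites).loc["t1"]
        assert np.allclose(means, taxon.baseline_abundance, rtol=1e-9)

    def test_poisson_means_recovered_monte_carlo(self, rng):
        # two sites engineered to have expected counts 5 and 0.5
        offset = np.sqrt(2 * np.log(10.0))  # Gaussian factor 0.1 at breadth 1
        sites = [
            SiteRecord("s1", "regional", 10.0, 90.0),
            SiteRecord("s2", "regional", 10.0 + offset, 90.0),
        ]
        taxon = make_taxon(breadth=(1.0, 1e9), baseline=5.0)
        reps = 1000
        totals = np.zeros(2)
        for _ in range(reps):
            totals += generate_abundances([taxon], sites, rng).loc["t1"].to_numpy()
        for mean, expected in zip(totals / reps, (5.0, 0.5)):
            se = np.sqrt(expected / reps)
            assert abs(mean - expected) < 3 * se

    def test_empty_site_list_errors(self, rng):
        with pytest.raises(ValueError, match="empty site"):
            generate_abundances([make_taxon()], [], rng)


class TestInteractions:
    @staticmethod
    def _two_level_setup(theta=0.0, gamma=0.0, **kwargs):
        config = SimulationConfig(
            n_sites=6, n_plants=2, n_animals=2, coupling_theta=theta, matching_gamma=gamma,
            total_interactions=200, seed=5, temperature_noise_sd=0.0, **kwargs
        )
        sites = generate_sites(config)
        plants = [make_taxon("p1", "plant"), make_taxon("p2", "plant", optimum=(12.0, 60.0))]
        animals = [make_taxon("a1", "animal"), make_taxon("a2", "animal", optimum=(8.0, 120.0))]
        p_ab = generate_abundances(plants, sites, stream_rng(config.seed, "plant_abundance"))
        a_ab = generate_abundances(animals, sites, stream_rng(config.seed, "animal_abundance"))
        return config, sites, plants, animals, p_ab, a_ab

    def test_null_coupling_rates_are_pure_abundance_products(self):
        config, sites, plants, animals, p_ab, a_ab = self._two_level_setup()
        rates = interaction_rates(p_ab, a_ab, animals, plants, config)
        expected = a_ab.to_numpy().T[:, :, None] * p_ab.to_numpy().T[:, None, :]
        assert np.allclose(rates, expected)

    def test_same_seed_reproduces_interaction_matrix(self):
        config, sites, plants, animals, p_ab, a_ab = self._two_level_setup(theta=1.0)
        m1, _ = generate_interactions(p_ab, a_ab, animals, plants, config, np.random.default_rng(9))
        m2, _ = generate_interactions(p_ab, a_ab, animals, plants, config, np.random.default_rng(9))
        pd.testing.assert_frame_equal(m1, m2)

    def test_aggregate_margins_equal_per_site_sums(self):
        config, sites, plants, animals, p_ab, a_ab = self._two_level_setup(theta=0.5)
        agg, per_site = generate_interactions(p_ab, a_ab, animals, plants, config, np.random.default_rng(2))
        assert agg.to_numpy().sum() == config.total_interactions
        per_site_agg = per_site.groupby(["animal", "plant"])["count"].sum()
        for (i, j), count in per_site_agg.items():
            assert agg.loc[i, j] == count

    def test_strong_coupling_suppresses_cross_extreme_pairs(self):
        # one cold-adapted and one warm-adapted pair at opposite gradient ends
        config = SimulationConfig(
            n_sites=6, n_plants=2, n_animals=2, coupling_theta=40.0,
            total_interactions=50, seed=5, temperature_noise_sd=0.0,
        )
        sites = generate_sites(config)
        narrow = (2.0, 1e9)
        plants = [
            make_taxon("p_cold", "plant", optimum=(5.0, 90.0), breadth=narrow),
            make_taxon("p_warm", "plant", optimum=(15.0, 90.0), breadth=narrow),
        ]
        animals = [
            make_taxon("a_cold", "animal", optimum=(5.0, 90.0), breadth=narrow),
            make_taxon("a_warm", "animal", optimum=(15.0, 90.0), breadth=narrow),
        ]
        rng = np.random.default_rng(77)
        cross = total = 0
        for _ in range(500):
            p_ab = generate_abundances(plants, sites, rng)
            a_ab = generate_abundances(animals, sites, rng)
            try:
                agg, _ = generate_interactions(p_ab, a_ab, animals, plants, config, rng)
            except ValueError:
                continue
            cross += agg.loc["a_cold", "p_warm"] + agg.loc["a_warm", "p_cold"]
            total += agg.to_numpy().sum()
        assert cross / total < 0.05

    def test_all_zero_rates_raise(self):
        config, sites, plants, animals, p_ab, a_ab = self._two_level_setup()
        with pytest.raises(ValueError, match="no co-occurring"):
            generate_interactions(p_ab * 0, a_ab, animals, plants, config, np.random.default_rng(0))


class TestStudy:
    def test_study_is_deterministic_and_schema_complete(self, tmp_path):
        config = SimulationConfig(seed=3, n_plants=6, n_animals=4, total_interactions=300)
        study1 = generate_study(config)
        study2 = generate_study(config)
        pd.testing.assert_frame_equal(study1.regional.interactions, study2.regional.interactions)
        paths = write_community(study1, tmp_path)
        expected_cols = {
            "sites": ["site_id", "scale", "temperature", "aspect"],
            "abundance": ["taxon", "site", "value"],
            "traits": ["taxon", "individual", "trait", "value"],
            "interactions": ["animal", "plant", "site", "count"],
            "pollen": ["species", "individual", "head", "thorax", "abdomen", "legs"],
            "taxonomy": ["species", "family"],
        }
        for name, cols in expected_cols.items():
            frame = pd.read_csv(paths[name])
            assert list(frame.columns) == cols

    def test_edge_length_inputs_positions_cover_matrix_taxa(self):
        config = SimulationConfig(seed=11, n_plants=6, n_animals=4, total_interactions=300)
        matrix, positions = edge_length_inputs(config)
        assert set(matrix.index) <= set(positions.index)
        assert set(matrix.columns) <= set(positions.index)
        values = positions.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_extreme_optima_yield_higher_marginality_than_central(self):
        # parameter recovery: rank order of |optimum − center| vs marginality
        from scipy import stats as sps

        from nicheweb.niche_spaces import build_weighted_cloud, marginality, niche_position
        from nicheweb.preprocessing import standardize_columns
        from nicheweb.synthetic_community import sites_frame

        offsets, margs = [], []
        for seed in range(6):
            config = SimulationConfig(seed=seed, env_breadth=(4.0, 72.0))
            taxa = [t for t in generate_taxa(config) if t.trophic_level == "plant"]
            sites = generate_sites(config)
            ab = generate_abundances(taxa, sites, stream_rng(config.seed, "plant_abundance"))
            env = standardize_columns(sites_frame(sites).set_index("site_id")[["temperature", "aspect"]])
            positions, offs = {}, {}
            for t in taxa:
                if ab.loc[t.taxon_id].sum() == 0:
                    continue
                positions[t.taxon_id] = niche_position(build_weighted_cloud(t.taxon_id, env, ab.loc[t.taxon_id]))
                offs[t.taxon_id] = np.linalg.norm(
                    (np.array(t.env_optimum) - np.array([10.0, 90.0])) / np.array([10.0, 180.0])
                )
            m = marginality(pd.DataFrame(positions).T)
            offsets.extend(offs[k] for k in m.index)
            margs.extend(m.values)
        assert sps.spearmanr(offsets, margs).statistic > 0
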