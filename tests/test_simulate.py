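"""Determinism, distributional fidelity, and bias mechanics of the
synthetic-table generator."""
import numpy as np
import pytest

from crisprstat import (
    SimulationConfig,
    associate_arrays,
    filter_dataset,
    fit_geometric,
    multiplicity_curve,
    profile_genomes,
    simulate_dataset,
    simulate_positions,
    single_cas_fraction,
    uniformity_test,
    write_array_table,
    write_cas_table,
)
from crisprstat.simulate import (
    biased_geometric_p,
    inject_proximal_bias,
    proximal_shrinkage,
    truncated_geometric,
    truncated_geometric_mean,
)


class TestConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_arrays_weights={1: 0.5, 2: 0.2})

    def test_length_range_ordering(self):
        with pytest.raises(ValueError):
            SimulationConfig(replicon_length_range=(5, 5))

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimulationConfig(n_genomes=7, seed=3, position_model="clustered")
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(path) == cfg


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        for run in ("a", "b"):
            arrays, operons = simulate_dataset(SimulationConfig(n_genomes=30, seed=9))
            write_array_table(arrays, tmp_path / f"arrays_{run}.tsv")
            write_cas_table(operons, tmp_path / f"cas_{run}.tsv")
        assert (tmp_path / "arrays_a.tsv").read_bytes() == (
            tmp_path / "arrays_b.tsv").read_bytes()
        assert (tmp_path / "cas_a.tsv").read_bytes() == (
            tmp_path / "cas_b.tsv").read_bytes()

    def test_zero_genomes_gives_empty_tables(self):
        arrays, operons = simulate_dataset(SimulationConfig(n_genomes=0))
        assert arrays == [] and operons == []


class TestTruncatedGeometric:
    def test_mean_matches_theory(self):
        """10,000 truncated draws at p = 0.025 land within 3 standard
        errors of the truncated-geometric mean."""
        rng = np.random.default_rng(21)
        draws = truncated_geometric(rng, 0.025, 10_000, 1)
        expected = truncated_geometric_mean(0.025, 1)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se
        assert draws.min() >= 1

    def test_untruncated_mode(self):
        rng = np.random.default_rng(22)
        draws = truncated_geometric(rng, 0.5, 5_000, 0)
        assert draws.min() == 0
        assert abs(draws.mean() - 1.0) < 0.1


class TestPositions:
    def test_mass_zero_is_uniform(self):
        deg = simulate_positions(1000, "clustered", cluster_mass=0.0, seed=5)
        assert uniformity_test(deg).p_value > 0.01

    def test_mass_one_confined_to_window(self):
        deg = simulate_positions(500, "clustered", cluster_center_deg=100,
                                 cluster_mass=1.0, cluster_width_deg=10, seed=6)
        assert np.all((deg >= 95) & (deg <= 105))

    def test_wrap_across_origin(self):
        deg = simulate_positions(2000, "clustered", cluster_center_deg=355,
                                 cluster_mass=1.0, cluster_width_deg=20, seed=7)
        in_window = ((deg >= 345) & (deg < 360)) | (deg < 5)
        assert np.all(in_window)
        assert (deg < 5).any() and (deg >= 345).any()


class TestProximalBias:
    def test_zero_bias_is_identity(self):
        sizes = np.array([10, 20, 30])
        out = inject_proximal_bias(sizes, [True, False, False], [3, 3, 3],
                                   p_geometric=0.025, proximal_bias=0.0, seed=1)
        assert np.array_equal(out, sizes)

    def test_shrinkage_factor(self):
        assert proximal_shrinkage(1.0, 4) == pytest.approx(8.0)
        assert proximal_shrinkage(0.5, 1) == 1.0

    def test_biased_mean_matches_monte_carlo(self):
        """With bias 1.0 and 4 arrays the proximal mean shrinks 8-fold."""
        p, bias, m = 0.025, 1.0, 4
        p_eff = biased_geometric_p(p, bias, m)
        target = (1 - p) / p / 8
        assert (1 - p_eff) / p_eff == pytest.approx(target)
        rng = np.random.default_rng(30)
        draws = rng.geometric(p_eff, 20_000) - 1
        assert abs(draws.mean() - target) < 3 * draws.std() / np.sqrt(draws.size)

    def test_stronger_bias_lowers_largest_proximal_proportion(self):
        """Sweeping the bias upward pushes the proportion of
        largest-proximal genomes down at every multiplicity >= 2."""
        props = []
        for bias in (0.0, 0.5, 2.0):
            cfg = SimulationConfig(n_genomes=400, seed=33, proximal_bias=bias,
                                   questionable_prob=0, plasmid_prob=0)
            arrays, operons = simulate_dataset(cfg)
            af, of = filter_dataset(arrays, operons)
            systems, _ = associate_arrays(of, af)
            profiles = profile_genomes(systems, af)
            curve = multiplicity_curve(profiles).set_index("n_arrays")
            multi = curve.loc[curve.index >= 2]
            props.append(
                multi["n_proximal_largest"].sum() / multi["n_genomes"].sum())
        assert props[0] > props[1] > props[2]


class TestFidelity:
    def test_geometric_parameter_recovered_at_scale(self):
        """fit_geometric on ~5,000 simulated sizes recovers p within
        +/- 0.005 (truncation at one spacer included)."""
        cfg = SimulationConfig(n_genomes=2400, seed=55, questionable_prob=0,
                               plasmid_prob=0)
        arrays, _ = simulate_dataset(cfg)
        counts = np.array([a.n_spacers for a in arrays])
        assert counts.size > 4000
        assert abs(fit_geometric(counts).theta - cfg.p_geometric) < 0.005

    def test_single_cas_fraction_near_configured_mass(self):
        from collections import Counter

        cfg = SimulationConfig(n_genomes=800, seed=56)
        _, operons = simulate_dataset(cfg)
        fraction = single_cas_fraction(Counter(o.accession for o in operons))
        # binomial SE at n = 800 is ~0.014; allow 3 SE
        assert abs(fraction - 0.82) < 0.045

    def test_tables_pass_io_validation(self, small_dataset, tmp_path):
        from crisprstat import read_array_table, read_cas_table

        arrays, operons = small_dataset
        write_array_table(arrays, tmp_path / "arrays.tsv")
        write_cas_table(operons, tmp_path / "cas.tsv")
        assert read_array_table(tmp_path / "arrays.tsv") == arrays
        assert read_cas_table(tmp_path / "cas.tsv") == operons
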