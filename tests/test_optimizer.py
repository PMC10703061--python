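"""AOA schedules, binarization rules, literal moves, wrapper fitness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbscreen.core import FeatureTable
from rbscreen.optimizer import (AOAConfig, FitnessConfig, aoa_position_update,
                                binarize_position, init_population,
                                literal_neighbor, moa_value, mop_value,
                                optimize_bits, optimize_selection,
                                transfer_probability, wrapper_fitness)
from rbscreen.synthetic import SyntheticTableSpec, generate_feature_table


class QueuedRng:
    """Deterministic stand-in for a Generator: returns queued uniforms."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        if size is None:
            return self.values.pop(0)
        n = int(np.prod(size))
        out = np.array([self.values.pop(0) for _ in range(n)]).reshape(size)
        return out

    def integers(self, *a, **kw):  # pragma: no cover - not used here
        raise NotImplementedError


class TestInitPopulation:
    def test_within_bounds(self):
        cfg = AOAConfig(seed=1)
        pop = init_population(cfg, 12)
        assert pop.shape == (cfg.population_size, 12)
        assert pop.min() >= 0.0 and pop.max() <= 1.0

    def test_degenerate_bounds_collapse(self):
        cfg = AOAConfig(lower_bound=0.5, upper_bound=0.5)
        assert np.allclose(init_population(cfg, 5), 0.5)

    def test_seeded_determinism(self):
        cfg = AOAConfig(seed=11)
        assert np.array_equal(init_population(cfg, 6), init_population(cfg, 6))

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            init_population(AOAConfig(), 0)


class TestSchedules:
    def test_moa_endpoints_and_midpoint(self):
        cfg = AOAConfig(moa_min=0.2, moa_max=0.9, max_iterations=100)
        assert moa_value(0, cfg) == pytest.approx(0.2)
        assert moa_value(100, cfg) == pytest.approx(0.9)
        assert moa_value(50, cfg) == pytest.approx(0.55)

    def test_moa_out_of_range(self):
        with pytest.raises(ValueError):
            moa_value(101, AOAConfig(max_iterations=100))

    def test_mop_endpoint_and_linear_case(self):
        assert mop_value(100, AOAConfig(max_iterations=100)) == pytest.approx(0.0)
        cfg = AOAConfig(max_iterations=100, alpha=1.0)
        assert mop_value(50, cfg) == pytest.approx(0.5)

    def test_mop_monotone_non_increasing(self):
        for alpha in (0.5, 1.0, 5.0):
            cfg = AOAConfig(max_iterations=50, alpha=alpha)
            vals = [mop_value(L, cfg) for L in range(1, 51)]
            assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestPositionUpdate:
    def test_division_branch_value(self):
        cfg = AOAConfig()
        # r1=0.99 > moa=0.5 -> explore; r2=0.1 < 0.5 -> division
        got = aoa_position_update(0.3, 0.5, 0.5, 0.5, cfg, QueuedRng([0.99, 0.1]))
        assert got == pytest.approx(0.5 / (0.5 + 1e-6) * 0.499, abs=1e-9)

    def test_multiplication_branch_value(self):
        cfg = AOAConfig()
        got = aoa_position_update(0.3, 0.5, 0.5, 0.5, cfg, QueuedRng([0.99, 0.9]))
        assert got == pytest.approx(0.5 * 0.5 * 0.499, abs=1e-12)

    def test_subtraction_and_addition_branches(self):
        cfg = AOAConfig()
        sub = aoa_position_update(0.3, 0.5, 0.5, 0.5, cfg, QueuedRng([0.1, 0.1]))
        add = aoa_position_update(0.3, 0.5, 0.5, 0.5, cfg, QueuedRng([0.1, 0.9]))
        assert sub == pytest.approx(0.5 - 0.5 * 0.499, abs=1e-12)
        assert add == pytest.approx(0.5 + 0.5 * 0.499, abs=1e-12)

    def test_output_clipped_to_bounds(self, rng):
        cfg = AOAConfig()
        for _ in range(200):
            got = aoa_position_update(rng.random(), rng.random(), rng.random(),
                                      rng.random(), cfg, rng)
            assert 0.0 <= got <= 1.0


class TestTransferFunctions:
    def test_sigmoid_center(self):
        assert transfer_probability(0.0, "S") == pytest.approx(0.5)

    def test_vshape_center_and_symmetry(self):
        assert transfer_probability(0.0, "V") == pytest.approx(0.0)
        x = np.linspace(-3, 3, 31)
        assert np.allclose(transfer_probability(x, "V"),
                           transfer_probability(-x, "V"))

    @settings(max_examples=50, derandomize=True)
    @given(x=st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_both_transfers_map_into_unit_interval(self, x):
        assert 0.0 <= transfer_probability(x, "S") <= 1.0
        assert 0.0 <= transfer_probability(x, "V") <= 1.0

    def test_sigmoid_strictly_increasing(self):
        x = np.linspace(-6, 6, 100)
        s = transfer_probability(x, "S")
        assert (np.diff(s) > 0).all()
        assert ((s >= 0) & (s <= 1)).all()


class TestBinarize:
    def test_s_rule_saturation(self):
        cfg = AOAConfig(transfer_kind="S")
        pos = np.full(8, 1e6)
        bits = binarize_position(pos, "S", np.zeros(8), np.random.default_rng(0), cfg)
        assert (bits == 1).all()

    def test_v_rule_at_reference_keeps_bits(self):
        cfg = AOAConfig(transfer_kind="V")
        current = np.array([1, 0, 1, 0], dtype=np.int8)
        pos = np.full(4, 0.5)  # at the domain center -> zero flip probability
        bits = binarize_position(pos, "V", current, np.random.default_rng(0), cfg)
        assert np.array_equal(bits, current)

    def test_s_rule_empirical_frequency(self):
        cfg = AOAConfig(transfer_kind="S")
        gain = cfg.effective_transfer_gain
        target = 0.7
        coord = 0.5 + np.log(target / (1 - target)) / gain
        pos = np.full(10_000, coord)
        bits = binarize_position(pos, "S", np.zeros(10_000),
                                 np.random.default_rng(42), cfg)
        assert bits.mean() == pytest.approx(target, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binarize_position(np.zeros(3), "S", np.zeros(4), np.random.default_rng(0))


class TestLiteralNeighbor:
    def test_s_move_single_flip(self, rng):
        bits = (rng.random(30) < 0.5).astype(np.int8)
        out = literal_neighbor(bits, "S", rng)
        assert np.sum(out != bits) == 1

    def test_v_move_is_xor_with_drawn_vector(self):
        bits = np.array([1, 0, 1, 0], dtype=np.int8)
        # uniforms below p_flip=0.5 mark flips: v = [0, 1, 1, 0]
        out = literal_neighbor(bits, "V", QueuedRng([0.9, 0.1, 0.1, 0.9]), p_flip=0.5)
        assert np.array_equal(out, [1, 1, 0, 0])

    def test_v_move_always_flips_something(self, rng):
        bits = np.zeros(10, dtype=np.int8)
        for _ in range(50):
            out = literal_neighbor(bits, "V", rng)
            assert out.size == 10 and (out != bits).any()


class TestWrapperFitness:
    def _separable_table(self, rng, n=60, d=6):
        X = rng.standard_normal((n, d))
        y = np.array(["healthy", "tumor"] * (n // 2))
        X[y == "tumor"] += 8.0  # far separated -> k-NN error 0
        return FeatureTable(X, y, [f"f{i}" for i in range(d)])

    def test_perfect_classifier_full_subset(self, rng):
        table = self._separable_table(rng)
        f = wrapper_fitness(np.ones(6, dtype=np.int8), table, FitnessConfig())
        assert f == pytest.approx(0.01)

    def test_empty_subset_penalty(self, rng):
        table = self._separable_table(rng)
        f = wrapper_fitness(np.zeros(6, dtype=np.int8), table, FitnessConfig())
        assert f == pytest.approx(0.99)

    def test_informative_subset_beats_noise_subset(self):
        table = generate_feature_table(SyntheticTableSpec(
            n_samples=150, n_features=30, n_informative=5, effect_size=2.0, seed=3))
        info = table.informative_mask.astype(np.int8)
        noise = np.zeros(30, dtype=np.int8)
        noise[np.where(~table.informative_mask)[0][:5]] = 1
        cfg = FitnessConfig(seed=0)
        assert wrapper_fitness(info, table, cfg) < wrapper_fitness(noise, table, cfg)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        table = FeatureTable(X, np.array(["healthy"] * 20), list("abcd"))
        with pytest.raises(ValueError):
            wrapper_fitness(np.ones(4, dtype=np.int8), table)


class TestOptimize:
    def onemax(self, bits):
        return 1.0 - bits.sum() / bits.size

    @pytest.mark.parametrize("mode", ["transfer", "literal"])
    @pytest.mark.parametrize("kind", ["S", "V"])
    def test_elite_history_non_increasing(self, mode, kind):
        cfg = AOAConfig(population_size=10, max_iterations=50, update_mode=mode,
                        transfer_kind=kind, seed=2)
        res = optimize_bits(self.onemax, 15, cfg)
        assert (np.diff(res.history) <= 0).all()
        assert len(res.history) <= cfg.max_iterations + 1

    @pytest.mark.parametrize("mode", ["transfer", "literal"])
    def test_identical_seeds_identical_results(self, mode):
        cfg = AOAConfig(population_size=8, max_iterations=30, update_mode=mode, seed=5)
        a = optimize_bits(self.onemax, 12, cfg)
        b = optimize_bits(self.onemax, 12, cfg)
        assert np.array_equal(a.best.bits, b.best.bits)
        assert np.array_equal(a.history, b.history)
        assert a.n_evaluations == b.n_evaluations

    @pytest.mark.parametrize("kind", ["S", "V"])
    def test_transfer_mode_solves_small_onemax(self, kind):
        cfg = AOAConfig(population_size=20, max_iterations=100,
                        transfer_kind=kind, seed=0)
        res = optimize_bits(self.onemax, 12, cfg)
        assert res.best_fitness == 0.0

    def test_selection_on_table_runs(self):
        table = generate_feature_table(SyntheticTableSpec(
            n_samples=60, n_features=12, n_informative=3, effect_size=2.5, seed=1))
        res = optimize_selection(table,
                                 AOAConfig(population_size=6, max_iterations=10, seed=0),
                                 FitnessConfig(seed=0))
        assert res.best.bits.size == 12
        assert res.best.fitness is not None
        assert res.n_evaluations >= 6
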